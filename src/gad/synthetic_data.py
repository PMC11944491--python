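"""Synthetic microbial community generator with ground truth.

Emulates the statistical structure the analysis assumes, end to end:

* a hierarchical reference taxonomy whose ranks separate at the calibrated
  identity bands (within-species >= 97%, within-genus [93, 97), within-family
  [89, 93), cross-family below 89%),
* environment-structured amplicon samples with lognormal within-sample
  abundances, read-level substitution noise and an exactly planted singleton
  fraction,
* a partially overlapping metagenome-style target set whose coverage
  probability grows with a species' occupancy class.

Mutation is substitution-only, so identity is predictable from substitution
counts; every generated reference set is verified against its bands by
measuring pairwise identities and resampling offending branches.
All randomness flows from ``SimulationConfig.seed``; identical configs give
byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .io_formats import (
    ENVIRONMENTS,
    AlignedSeqRecord,
    SeqRecord,
    TaxonomyLabel,
)
from .region_prep import RegionSpec
from .similarity import ReferenceDB, pairwise_identity

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic survey.

    Divergence fractions are per-branch substitution rates chosen so that
    leaf pairs land in the upper half of their rank band at the default
    sequence length (see docs/methods.md for the arithmetic).
    """

    seed: int = 0
    n_families: int = 10
    genera_per_family: int = 3
    species_per_genus: int = 4
    sequence_length: int = 250
    variants_per_species: int = 1  # 1 or 2 reference records per species

    # per-branch substitution fractions
    family_branch: float = 0.036
    genus_branch: float = 0.02
    species_branch: float = 0.032
    variant_distance: float = 0.028

    # rank identity bands in percent (low inclusive, high exclusive)
    species_band: Tuple[float, float] = (97.0, 100.001)
    genus_band: Tuple[float, float] = (93.0, 97.0)
    family_band: Tuple[float, float] = (89.0, 93.0)
    max_retries: int = 100

    # sampling design
    environments: Dict[str, int] = field(
        default_factory=lambda: {
            "host": 10, "plant": 10, "soil": 10, "freshwater": 10,
            "saline_water": 10,
        }
    )
    env_exclusive_fraction: Dict[str, float] = field(
        default_factory=lambda: {
            "saline_water": 0.30, "soil": 0.20, "freshwater": 0.10,
            "host": 0.05, "plant": 0.05,
        }
    )
    species_per_sample: int = 12
    abundance_mu: float = 1.0
    abundance_sigma: float = 1.0
    singleton_fraction: float = 0.10
    noise_rate: float = 0.002
    dirichlet_alpha: float = 0.5
    ensure_coverage: bool = True  # every species appears in >=1 sample

    # alignment emission
    alignment_gap_columns: int = 50

    # metagenome target set
    metagenome_coverage: Dict[str, float] = field(
        default_factory=lambda: {
            "singleton": 0.05, "doubleton": 0.30, "tripleton": 0.35,
            "moreton": 0.60,
        }
    )
    metagenome_noise_rate: float = 0.002

    def __post_init__(self):
        if self.variants_per_species not in (1, 2):
            raise ValueError("variants_per_species must be 1 or 2")
        bands = [self.family_band, self.genus_band, self.species_band]
        for (lo, hi) in bands:
            if not lo < hi:
                raise ValueError(f"band ({lo}, {hi}) not ordered")
        if not (self.family_band[1] <= self.genus_band[0] + 1e-9
                and self.genus_band[1] <= self.species_band[0] + 1e-9):
            raise ValueError("rank bands must be ordered and non-overlapping")
        for env in self.environments:
            if env not in ENVIRONMENTS:
                raise ValueError(f"unknown environment {env!r}")
        for p in list(self.metagenome_coverage.values()) + [
            self.noise_rate, self.metagenome_noise_rate, self.singleton_fraction,
        ]:
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class SyntheticTruth:
    """Generator ground truth for parameter-recovery tests."""

    # record id -> (family, genus, species) names; covers refdb and reads
    taxonomy: Dict[str, Tuple[str, str, str]] = field(default_factory=dict)
    # species id -> environment affinity vector (env -> weight)
    species_affinity: Dict[str, Dict[str, float]] = field(default_factory=dict)
    planted_singletons: List[str] = field(default_factory=list)
    # species id -> samples it was emitted into
    species_samples: Dict[str, Set[str]] = field(default_factory=dict)
    # species id -> included in the metagenome target set
    target_db_membership: Dict[str, bool] = field(default_factory=dict)
    region: Optional[RegionSpec] = None
    gap_columns: Optional[List[int]] = None


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


def _mutate(rng, seq: np.ndarray, positions: np.ndarray) -> np.ndarray:
    """Substitute each position with a uniformly random *different* base."""
    out = seq.copy()
    for p in positions:
        choices = _BASES[_BASES != out[p]]
        out[p] = rng.choice(choices)
    return out


def _decode(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def _hamming_identity(a: np.ndarray, b: np.ndarray) -> float:
    return 100.0 * float((a == b).mean())


class _Leaf:
    __slots__ = ("species", "kind", "fam", "gen", "seq")

    def __init__(self, species, kind, fam, gen, seq):
        self.species = species
        self.kind = kind  # "base" | "variant"
        self.fam = fam
        self.gen = gen
        self.seq = seq


def simulate_reference_taxonomy(
    config: SimulationConfig,
) -> Tuple[ReferenceDB, SyntheticTruth]:
    """Generate a band-calibrated reference taxonomy.

    Family, genus and species ancestors are derived by fixed numbers of
    random substitutions per branch; with ``variants_per_species=2`` each
    species also gets one variant at the species-band edge (half of its
    substitutions revert toward the genus ancestor so that cross-species
    distances are left unchanged).  Band membership of every leaf pair is
    verified with :func:`pairwise_identity` near the band edges and offending
    branches are resampled (up to ``max_retries`` rounds).
    """
    rng = _rng(config, 0)
    L = config.sequence_length
    k_f = max(1, round(config.family_branch * L))
    k_g = max(1, round(config.genus_branch * L))
    k_s = max(1, round(config.species_branch * L))
    k_v = max(1, round(config.variant_distance * L))
    if k_s + k_g + k_f >= L // 2:
        raise ValueError("divergence bands unachievable at this length")

    root = rng.choice(_BASES, size=L)
    gen_anc: Dict[Tuple[int, int], np.ndarray] = {}
    for fi in range(config.n_families):
        fam_anc = _mutate(rng, root, rng.choice(L, size=k_f, replace=False))
        for gi in range(config.genera_per_family):
            gen_anc[(fi, gi)] = _mutate(
                rng, fam_anc, rng.choice(L, size=k_g, replace=False)
            )

    def make_base(fi, gi):
        anc = gen_anc[(fi, gi)]
        return _mutate(rng, anc, rng.choice(L, size=k_s, replace=False))

    def make_variant(fi, gi, base):
        """Mutate at the species-band edge without moving cross-species
        distances: revert half the private substitutions, add the rest new."""
        anc = gen_anc[(fi, gi)]
        private = np.flatnonzero(base != anc)
        shared = np.flatnonzero(base == anc)
        n_rev = min(len(private), int(math.ceil(k_v / 2)))
        n_nov = k_v - n_rev
        out = base.copy()
        rev = rng.choice(private, size=n_rev, replace=False)
        out[rev] = anc[rev]
        nov = rng.choice(shared, size=n_nov, replace=False)
        out = _mutate(rng, out, nov)
        return out

    leaves: List[_Leaf] = []
    for fi in range(config.n_families):
        for gi in range(config.genera_per_family):
            for si in range(config.species_per_genus):
                sp = f"F{fi + 1:02d}.G{gi + 1}.S{si + 1}"
                base = make_base(fi, gi)
                leaves.append(_Leaf(sp, "base", fi, gi, base))
                if config.variants_per_species == 2:
                    leaves.append(
                        _Leaf(sp, "variant", fi, gi, make_variant(fi, gi, base))
                    )

    # --- verify bands, resampling offending branches ----------------------
    def band_for(a: _Leaf, b: _Leaf) -> Tuple[float, float]:
        if a.species == b.species:
            return config.species_band
        if (a.fam, a.gen) == (b.fam, b.gen):
            return config.genus_band
        if a.fam == b.fam:
            return config.family_band
        return (0.0, config.family_band[0])

    margin = 2.0  # DP identity can exceed Hamming identity, never undershoot

    def violators() -> Set[int]:
        bad: Set[int] = set()
        mat = np.stack([lf.seq for lf in leaves])
        for i in range(len(leaves)):
            for j in range(i + 1, len(leaves)):
                lo, hi = band_for(leaves[i], leaves[j])
                ham = _hamming_identity(mat[i], mat[j])
                if ham < lo or ham >= hi - margin:
                    dp = pairwise_identity(
                        _decode(mat[i]), _decode(mat[j])
                    ).identity_pct
                    if not (lo <= dp < hi):
                        bad.add(max(i, j))
        return bad

    for _ in range(config.max_retries):
        bad = violators()
        if not bad:
            break
        for idx in sorted(bad):
            lf = leaves[idx]
            if lf.kind == "base":
                lf.seq = make_base(lf.fam, lf.gen)
                # the variant derives from the base; refresh it too
                for other in leaves:
                    if other.species == lf.species and other.kind == "variant":
                        other.seq = make_variant(lf.fam, lf.gen, lf.seq)
            else:
                base = next(
                    o.seq for o in leaves
                    if o.species == lf.species and o.kind == "base"
                )
                lf.seq = make_variant(lf.fam, lf.gen, base)
    else:
        raise RuntimeError(
            "could not place all pairs inside their identity bands; "
            "bands may be unachievable at this sequence length"
        )

    records, taxonomy, truth = [], {}, SyntheticTruth()
    for lf in leaves:
        fam, gen, _ = lf.species.split(".")
        names = (fam, f"{fam}.{gen}", lf.species)
        rid = lf.species if lf.kind == "base" else lf.species + ".v2"
        records.append(
            SeqRecord(rid, _decode(lf.seq), {"refdb": 1}, source="reference")
        )
        taxonomy[rid] = TaxonomyLabel.from_ranks(
            {
                "domain": "Archaea",
                "phylum": "SimPhylum",
                "class": "SimClass",
                "order": "SimOrder",
                "family": names[0],
                "genus": names[1],
                "species": names[2],
            }
        )
        truth.taxonomy[rid] = names
    return ReferenceDB(records, taxonomy), truth


def _species_bases(db: ReferenceDB) -> Dict[str, str]:
    """species id -> base sequence (variant records excluded)."""
    return {
        r.id: r.sequence for r in db.records if not r.id.endswith(".v2")
    }


def simulate_dataset(
    db: ReferenceDB,
    truth: SyntheticTruth,
    config: SimulationConfig,
) -> Tuple[List[SeqRecord], Dict[str, Dict[str, int]], Dict[str, str], SyntheticTruth]:
    """Draw environment-structured amplicon samples from the reference set.

    Every sample draws species by its environment's affinity weights; each
    drawn species emits one read-level OTU with lognormal abundance and
    per-base substitution noise.  A ``singleton_fraction`` of species is
    planted into exactly one sample each.  Returns (records, provenance,
    sample metadata, truth).
    """
    rng = _rng(config, 1)
    bases = _species_bases(db)
    species = sorted(bases)
    n_species = len(species)

    # sample frame
    metadata: Dict[str, str] = {}
    for env in sorted(config.environments):
        for i in range(config.environments[env]):
            metadata[f"{env}_{i + 1:03d}"] = env
    samples = sorted(metadata)
    envs = sorted(config.environments)

    # planted singletons: exact count, one sample each
    n_single = int(math.floor(config.singleton_fraction * n_species))
    singles = list(rng.choice(species, size=n_single, replace=False))
    truth.planted_singletons = sorted(singles)
    pool = [s for s in species if s not in set(singles)]

    # Environment-exclusive species, then cosmopolitan remainder.  Exclusive
    # species are allocated in genus blocks (endemic diversity is clade-
    # structured), so a "novel" environment gains genus- and family-level
    # novelty, not only species-level novelty.
    exclusive: Dict[str, List[str]] = {}
    cursor = 0
    blocks: Dict[str, Dict[str, List[str]]] = {}
    for sp in pool:
        gen = sp.rsplit(".", 1)[0]
        fam = gen.split(".")[0]
        blocks.setdefault(fam, {}).setdefault(gen, []).append(sp)
    order = []
    for fam in rng.permutation(sorted(blocks)):
        for gen in rng.permutation(sorted(blocks[fam])):
            order.extend(blocks[fam][gen])
    for env in envs:
        n_excl = int(math.floor(config.env_exclusive_fraction.get(env, 0.0) * n_species))
        n_excl = min(n_excl, len(order) - cursor)
        exclusive[env] = order[cursor : cursor + n_excl]
        cursor += n_excl
    cosmopolitan = order[cursor:]

    for env in envs:
        for sp in exclusive[env]:
            truth.species_affinity[sp] = {e: float(e == env) for e in envs}
    for sp in cosmopolitan:
        w = rng.dirichlet([config.dirichlet_alpha] * len(envs))
        truth.species_affinity[sp] = dict(zip(envs, (float(x) for x in w)))

    def noisy(seq: str) -> str:
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
        if config.noise_rate > 0:
            hits = np.flatnonzero(rng.random(len(arr)) < config.noise_rate)
            arr = _mutate(rng, arr, hits)
        return arr.tobytes().decode("ascii")

    records: List[SeqRecord] = []
    provenance: Dict[str, Dict[str, int]] = {}

    def emit(sample: str, sp: str) -> None:
        count = int(math.ceil(rng.lognormal(config.abundance_mu, config.abundance_sigma)))
        otu = f"{sample}:{sp}"
        records.append(SeqRecord(otu, noisy(bases[sp]), {sample: count}))
        provenance[otu] = {sample: count}
        truth.species_samples.setdefault(sp, set()).add(sample)
        if sp in truth.taxonomy:
            truth.taxonomy[otu] = truth.taxonomy[sp]
        else:  # derive names from the species id (F01.G2.S3 convention)
            fam, gen, _ = sp.split(".")
            truth.taxonomy[otu] = (fam, f"{fam}.{gen}", sp)

    drawable = [sp for sp in species if sp not in set(singles)]
    for sample in samples:
        env = metadata[sample]
        weights = np.array(
            [truth.species_affinity[sp].get(env, 0.0) for sp in drawable]
        )
        positive = int((weights > 0).sum())
        if positive == 0:
            continue
        k = min(config.species_per_sample, positive)
        drawn = rng.choice(
            drawable, size=k, replace=False, p=weights / weights.sum()
        )
        for sp in sorted(drawn):
            emit(sample, sp)

    for sp in singles:
        emit(str(rng.choice(samples)), sp)

    if config.ensure_coverage:
        # sweep species the affinity draws missed into one sample each
        for sp in species:
            if sp in truth.species_samples:
                continue
            weights = np.array(
                [truth.species_affinity[sp].get(metadata[s], 0.0) for s in samples]
            )
            if weights.sum() == 0:
                weights = np.ones(len(samples))
            emit(str(rng.choice(samples, p=weights / weights.sum())), sp)

    # fixed shared gap-column pattern for the aligned emission
    aln_len = config.sequence_length + config.alignment_gap_columns
    gap_cols = sorted(
        int(x)
        for x in rng.choice(aln_len, size=config.alignment_gap_columns, replace=False)
    )
    truth.gap_columns = gap_cols
    truth.region = RegionSpec(
        start_col=1,
        end_col=aln_len,
        min_informative_bases=min(244, config.sequence_length),
    )
    return records, provenance, metadata, truth


def aligned_records(
    records: Sequence[SeqRecord], truth: SyntheticTruth
) -> List[AlignedSeqRecord]:
    """Insert the study's shared gap-column pattern into gap-free records."""
    if truth.gap_columns is None:
        raise ValueError("truth carries no gap pattern; run simulate_dataset first")
    gap_set = set(truth.gap_columns)
    aln_len = len(truth.gap_columns) + len(records[0].sequence)
    out = []
    for r in records:
        chars, it = [], iter(r.sequence)
        for col in range(aln_len):
            chars.append("-" if col in gap_set else next(it))
        out.append(AlignedSeqRecord(r.id, "".join(chars)))
    return out


def occupancy_of(n_samples: int) -> str:
    from .clustering import OCCUPANCY_CLASSES

    return OCCUPANCY_CLASSES[min(n_samples, 4) - 1]


def simulate_metagenome_refs(
    db: ReferenceDB,
    truth: SyntheticTruth,
    config: SimulationConfig,
) -> List[SeqRecord]:
    """Build the metagenome-derived target set.

    Each species observed in the dataset enters with the coverage probability
    of its occupancy class (cosmopolitan species are overrepresented in
    metagenome collections); included sequences carry light substitution
    noise so matches land near but not at 100%.
    """
    rng = _rng(config, 2)
    bases = _species_bases(db)
    out: List[SeqRecord] = []
    for sp in sorted(bases):
        samples = truth.species_samples.get(sp)
        if not samples:
            truth.target_db_membership[sp] = False
            continue
        p = config.metagenome_coverage[occupancy_of(len(samples))]
        include = bool(rng.random() < p)
        truth.target_db_membership[sp] = include
        if include:
            arr = np.frombuffer(bases[sp].encode("ascii"), dtype=np.uint8).copy()
            if config.metagenome_noise_rate > 0:
                hits = np.flatnonzero(
                    rng.random(len(arr)) < config.metagenome_noise_rate
                )
                arr = _mutate(rng, arr, hits)
            out.append(
                SeqRecord(
                    f"mg|{sp}",
                    arr.tobytes().decode("ascii"),
                    {"metagenome": 1},
                    source="reference",
                )
            )
    return out


def simulate_study(config: SimulationConfig):
    """Convenience wrapper: reference taxonomy, dataset and metagenome target
    set in one call.  Returns (db, records, provenance, metadata, targets,
    truth)."""
    db, truth = simulate_reference_taxonomy(config)
    records, provenance, metadata, truth = simulate_dataset(db, truth, config)
    targets = simulate_metagenome_refs(db, truth, config)
    return db, records, provenance, metadata, targets, truth
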