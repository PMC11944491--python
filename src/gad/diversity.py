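"""Diversity estimators over a tiered cluster set.

Includes the conservative lower bound (most abundant SOTU per GOTU per
sample), sample-accumulation rarefaction with the marginal discovery rate
d_sotu, per-environment novelty scores, environment assignment of clusters,
and per-taxon summary tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Set, Tuple

import numpy as np

from .clustering import Cluster, TieredClusterSet
from .io_formats import SeqRecord, TaxonomyLabel


def sotu_sample_abundance(
    tiered: TieredClusterSet, records: Sequence[SeqRecord]
) -> Dict[str, Dict[str, int]]:
    """Per-SOTU per-sample abundance, summed over member records."""
    by_id = {r.id: r for r in records}
    out: Dict[str, Dict[str, int]] = {}
    for c in tiered.species_clusters:
        counts: Dict[str, int] = {}
        for mid in c.member_ids:
            for sample, n in by_id[mid].sample_counts.items():
                counts[sample] = counts.get(sample, 0) + n
        out[c.centroid_id] = counts
    return out


def conservative_lower_bound(
    tiered: TieredClusterSet,
    provenance: Mapping[str, Mapping[str, int]],
) -> Tuple[int, Set[str]]:
    """Count SOTUs after keeping, per (sample, GOTU), only the most abundant
    SOTU in that sample.

    Two SOTUs of the same GOTU seen in one sample are assumed to differ by
    noise rather than biology, so only the dominant one is trusted.  Ties
    break to the lexicographically smallest SOTU id.  Returns (count, kept
    SOTU ids).
    """
    # (sample, gotu) -> best (abundance, sotu id)
    best: Dict[Tuple[str, str], Tuple[int, str]] = {}
    for sotu, per_sample in provenance.items():
        gotu = tiered.sotu_to_gotu[sotu]
        for sample, count in per_sample.items():
            key = (sample, gotu)
            cur = best.get(key)
            if cur is None or (-count, sotu) < (-cur[0], cur[1]):
                best[key] = (count, sotu)
    kept = {sotu for _, sotu in best.values()}
    return len(kept), kept


@dataclass
class RarefactionResult:
    n_samples: int
    mean_curve: List[float]  # expected distinct SOTUs after k samples, k=1..n
    permutations: int
    seed: int
    d_sotu: float


def rarefaction(
    sotu_by_sample: Mapping[str, Set[str]],
    R: int = 10,
    seed: int = 42,
) -> RarefactionResult:
    """Sample-accumulation curve averaged over R random sample orders.

    d_sotu is the mean number of SOTUs first contributed by the final sample
    of a permutation — the expected discovery yield of one additional sample.
    """
    samples = sorted(sotu_by_sample)
    if not samples:
        raise ValueError("rarefaction requires at least one sample")
    n = len(samples)
    rng = np.random.default_rng(seed)
    curves = np.zeros((R, n))
    for r in range(R):
        order = rng.permutation(n)
        seen: Set[str] = set()
        for k, idx in enumerate(order):
            seen |= sotu_by_sample[samples[idx]]
            curves[r, k] = len(seen)
    mean_curve = curves.mean(axis=0)
    d_sotu = float(
        (curves[:, -1] - curves[:, -2]).mean() if n > 1 else curves[:, -1].mean()
    )
    return RarefactionResult(n, [float(x) for x in mean_curve], R, seed, d_sotu)


def sotus_by_sample(tiered: TieredClusterSet, records: Sequence[SeqRecord]) -> Dict[str, Set[str]]:
    """sample id -> set of SOTU ids observed in that sample."""
    by_id = {r.id: r for r in records}
    out: Dict[str, Set[str]] = {}
    for c in tiered.species_clusters:
        for mid in c.member_ids:
            for sample in by_id[mid].samples:
                out.setdefault(sample, set()).add(c.centroid_id)
    return out


@dataclass
class NoveltyScore:
    environment: str
    n_samples: int
    sotu_score: float
    gotu_score: float
    fotu_score: float


def novelty_scores(
    tiered: TieredClusterSet, metadata: Mapping[str, str]
) -> List[NoveltyScore]:
    """Distinct clusters per level observed in an environment, divided by the
    environment's sample count.

    A cluster observed in several environments counts toward each of them.
    Environments with zero samples are omitted.
    """
    env_samples: Dict[str, Set[str]] = {}
    for sample, env in metadata.items():
        env_samples.setdefault(env, set()).add(sample)

    def observed(clusters: Sequence[Cluster], samples: Set[str]) -> int:
        return sum(1 for c in clusters if c.samples & samples)

    out = []
    for env in sorted(env_samples):
        samples = env_samples[env]
        n = len(samples)
        out.append(
            NoveltyScore(
                environment=env,
                n_samples=n,
                sotu_score=observed(tiered.species_clusters, samples) / n,
                gotu_score=observed(tiered.genus_clusters, samples) / n,
                fotu_score=observed(tiered.family_clusters, samples) / n,
            )
        )
    return out


def environment_assignment(
    cluster: Cluster,
    provenance: Mapping[str, Mapping[str, int]],
    metadata: Mapping[str, str],
) -> Tuple[str, str]:
    """(by_abundance, by_majority) environment of a cluster.

    by_abundance: environment of the sample contributing the single
    highest-abundance member occurrence (ties: smallest member id, then
    smallest sample id).  by_majority: most frequent environment over all
    member occurrences (ties: alphabetical environment name).
    """
    occurrences = []  # (count, member id, sample, env)
    for mid in cluster.member_ids:
        for sample, count in provenance.get(mid, {}).items():
            occurrences.append((count, mid, sample, metadata[sample]))
    if not occurrences:
        raise ValueError(f"cluster {cluster.centroid_id}: no provenance")
    top = min(occurrences, key=lambda o: (-o[0], o[1], o[2]))
    by_abundance = top[3]
    freq: Dict[str, int] = {}
    for _, _, _, env in occurrences:
        freq[env] = freq.get(env, 0) + 1
    by_majority = min(freq, key=lambda e: (-freq[e], e))
    return by_abundance, by_majority


def taxon_summary(
    tiered: TieredClusterSet,
    taxonomy: Mapping[str, TaxonomyLabel],
) -> List[dict]:
    """Per-taxon row: #sequences, #SOTUs, #GOTUs, #FOTUs, sotu_rate.

    ``taxonomy`` labels the clustered sequences (records).  sotu_rate =
    #SOTUs / #sequences; a low rate marks a narrow, sequence-rich taxon.
    """
    member_sotu: Dict[str, str] = {}
    for c in tiered.species_clusters:
        for mid in c.member_ids:
            member_sotu[mid] = c.centroid_id

    rows = []
    for rank in ("phylum", "class", "order", "family", "genus", "species"):
        taxa: Dict[str, Set[str]] = {}
        for sid, label in taxonomy.items():
            name = label.rank(rank)
            if name.startswith("UNK") or sid not in member_sotu:
                continue
            taxa.setdefault(name, set()).add(sid)
        for name in sorted(taxa):
            seqs = taxa[name]
            sotus = {member_sotu[s] for s in seqs}
            gotus = {tiered.sotu_to_gotu[s] for s in sotus}
            fotus = {tiered.gotu_to_fotu[g] for g in gotus}
            rows.append(
                {
                    "rank": rank,
                    "taxon": name,
                    "n_sequences": len(seqs),
                    "n_sotus": len(sotus),
                    "n_gotus": len(gotus),
                    "n_fotus": len(fotus),
                    "sotu_rate": len(sotus) / len(seqs),
                }
            )
    return rows


def plot_rarefaction(results: Mapping[str, RarefactionResult], path) -> None:
    """One accumulation curve per environment, with the 1:1 discovery line."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    top = 1
    for env, res in sorted(results.items()):
        xs = range(1, res.n_samples + 1)
        ax.plot(xs, res.mean_curve, label=f"{env} (d_sotu={res.d_sotu:.2f})")
        top = max(top, res.n_samples)
    ax.plot([0, top], [0, top], "k--", lw=0.8, label="1:1")
    ax.set_xlabel("# samples integrated")
    ax.set_ylabel("# distinct SOTUs")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_novelty(scores: Sequence[NoveltyScore], path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    envs = [s.environment for s in scores]
    x = np.arange(len(envs))
    fig, ax = plt.subplots(figsize=(6, 4))
    for off, (attr, label) in enumerate(
        [("sotu_score", "SOTU"), ("gotu_score", "GOTU"), ("fotu_score", "FOTU")]
    ):
        ax.bar(x + 0.25 * off, [getattr(s, attr) for s in scores], 0.25, label=label)
    ax.set_xticks(x + 0.25)
    ax.set_xticklabels(envs, rotation=30, ha="right")
    ax.set_ylabel("distinct clusters / sample")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
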