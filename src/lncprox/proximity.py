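"""Network proximity between candidate-protein modules and disease gene sets.

A candidate module is a seed protein together with its first neighbors in
the interactome.  Its proximity to a disease gene set T is the average
shortest network distance

    D = (1/|S|) * sum_{s in S} d_s,   d_s = (1/|T|) * sum_{t in T} d_st,

where d_st is the unweighted shortest-path length.  Significance is
assessed against a degree-preserving randomization null: N random gene sets
matched to the module's degree-bin profile are scored against the same T,
and the empirical p-value is the fraction of randomized distances strictly
below the observed one,

    p_emp = #{r : D_r < D} / N.

The granularity of this p-value is 1/N (the detection threshold); p_emp = 0
is rendered as "< 1/N".  Only the module set S is randomized; the disease
set T is held fixed.
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .interactome import DegreeBins, GeneSet, Interactome, build_degree_bins

logger = logging.getLogger(__name__)

__all__ = [
    "CandidateModule",
    "ProximityResult",
    "ProximityMatrix",
    "build_candidate_module",
    "average_module_distance",
    "mean_distance_to_targets",
    "sample_degree_matched_set",
    "proximity_significance",
    "proximity_matrix",
]


@dataclass(frozen=True)
class CandidateModule:
    """A seed protein plus its direct interaction partners (the set S)."""

    seed: str
    members: frozenset[str]

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class ProximityResult:
    candidate: str
    disease: str
    d_obs: float
    null_distances: np.ndarray = field(repr=False)
    n_randomizations: int
    p_emp: float
    p_conservative: float      # (count+1)/(N+1), reported but never used for masking
    below_detection: bool      # true iff p_emp == 0
    z_score: float | None      # None when the null distribution is degenerate
    n_module_mapped: int
    n_disease_mapped: int

    @property
    def detection_threshold(self) -> float:
        return 1.0 / self.n_randomizations

    @property
    def p_display(self) -> str:
        if self.below_detection:
            return f"<{self.detection_threshold:g}"
        return f"{self.p_emp:.3f}"


def build_candidate_module(g: Interactome, seed: str) -> CandidateModule:
    """Seed + first neighbors; errors with prefix suggestions if seed is absent."""
    if seed not in g:
        prefix = seed[:3]
        hints = sorted(n for n in g.nodes if n.startswith(prefix))[:5]
        raise KeyError(
            f"seed {seed!r} not in interactome"
            + (f"; nearest by prefix: {', '.join(hints)}" if hints else ""))
    members = g.neighbors(seed) | {seed}
    if len(members) == 1:
        logger.warning("seed %s has no neighbors; module is the seed alone", seed)
    return CandidateModule(seed=seed, members=frozenset(members))


def _map_into_graph(g: Interactome, symbols, label: str) -> set[str]:
    mapped = set(symbols) & g.nodes
    dropped = set(symbols) - mapped
    if dropped:
        logger.info("%s: %d symbol(s) not in graph, dropped: %s",
                    label, len(dropped), ", ".join(sorted(dropped)[:10]))
    if not mapped:
        raise ValueError(
            f"{label}: no symbols map into the graph "
            f"(dropped: {', '.join(sorted(dropped)[:10])})")
    return mapped


def mean_distance_to_targets(g: Interactome, T: set[str]) -> dict[str, float]:
    """For every node u reachable from all of T, the mean of d(u, t) over t in T.

    One BFS per target gene; the resulting vector lets any source set S be
    scored in O(|S|) lookups, which makes the N-fold randomization cheap.
    """
    if not T:
        raise ValueError("empty target set")
    acc: dict[str, float] | None = None
    for t in T:
        lengths = nx.single_source_shortest_path_length(g.graph, t)
        if acc is None:
            acc = {u: float(d) for u, d in lengths.items()}
        else:
            acc = {u: acc[u] + d for u, d in lengths.items() if u in acc}
    k = len(T)
    return {u: s / k for u, s in acc.items()}


def average_module_distance(g: Interactome, S, T) -> float:
    """The averaged shortest-distance statistic D between gene sets S and T.

    Symbols outside the graph are dropped (and counted in the log); a pair
    left unreachable raises, since distance is undefined across components
    -- run on the largest connected component.
    """
    S = _map_into_graph(g, S, "module set S")
    T = _map_into_graph(g, T, "disease set T")
    mdt = mean_distance_to_targets(g, T)
    try:
        # fixed summation order: float result independent of set iteration
        return float(np.mean([mdt[s] for s in sorted(S)]))
    except KeyError as e:
        raise ValueError(
            f"node {e.args[0]!r} cannot reach every disease gene; "
            "restrict the analysis to the largest connected component") from e


def sample_degree_matched_set(bins: DegreeBins, S, rng) -> set[str]:
    """Draw |S| distinct genes, one per module gene, uniformly from its degree bin.

    Genes of the original set are eligible.  Collisions cannot occur across
    bins (bins are disjoint), so distinctness is enforced by sampling
    without replacement within each bin.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    S = set(S)
    demand: dict[int, int] = {}
    for s in S:
        if s not in bins.assignment:
            raise KeyError(f"module gene {s!r} has no degree-bin assignment")
        bid = bins.bin_of(s)
        demand[bid] = demand.get(bid, 0) + 1
    out: set[str] = set()
    for bid in sorted(demand):
        members = sorted(bins.bin_members[bid])
        k = demand[bid]
        if k > len(members):
            raise ValueError(
                f"degree bin {bid} holds {len(members)} genes but must supply "
                f"{k} draws; rebuild bins with a smaller min_bin_size")
        out |= set(rng.choice(members, size=k, replace=False))
    return out


def proximity_significance(
    g: Interactome,
    module: CandidateModule,
    disease: GeneSet,
    n_randomizations: int = 250,
    rng_seed: int | np.random.Generator = 0,
    bins: DegreeBins | None = None,
    min_bin_size: int = 100,
) -> ProximityResult:
    """Observed D plus its degree-preserving randomization null.

    The disease set T is fixed; N degree-matched random sets replace the
    whole module (seed and neighbors).  p_emp counts strictly smaller
    randomized distances, so its value lies on the grid {0, 1/N, ..., 1}.
    """
    if n_randomizations < 1:
        raise ValueError("n_randomizations must be >= 1")
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    if bins is None:
        bins = build_degree_bins(g, min_bin_size=min_bin_size)

    S = _map_into_graph(g, module.members, f"module {module.seed}")
    T = _map_into_graph(g, disease.members, f"disease {disease.name}")
    mdt = mean_distance_to_targets(g, T)

    def score(genes: set[str]) -> float:
        try:
            # sorted so ties are bit-exact regardless of set iteration order
            return float(np.mean([mdt[x] for x in sorted(genes)]))
        except KeyError as e:
            raise ValueError(
                f"node {e.args[0]!r} cannot reach every disease gene; "
                "use the largest connected component") from e

    d_obs = score(S)
    null = np.empty(n_randomizations)
    for i in range(n_randomizations):
        null[i] = score(sample_degree_matched_set(bins, S, rng))

    count = int(np.sum(null < d_obs))
    p_emp = count / n_randomizations
    degenerate = n_randomizations < 2 or np.ptp(null) == 0
    sd = 0.0 if degenerate else float(np.std(null, ddof=1))
    z = None if degenerate else (d_obs - float(np.mean(null))) / sd
    return ProximityResult(
        candidate=module.seed,
        disease=disease.name,
        d_obs=d_obs,
        null_distances=null,
        n_randomizations=n_randomizations,
        p_emp=p_emp,
        p_conservative=(count + 1) / (n_randomizations + 1),
        below_detection=(count == 0),
        z_score=z,
        n_module_mapped=len(S),
        n_disease_mapped=len(T),
    )


@dataclass
class ProximityMatrix:
    """Candidate x disease grid of proximity results with a significance mask."""

    rows: list[str]
    cols: list[str]
    cells: dict[tuple[str, str], ProximityResult] = field(repr=False)
    significance_cutoff: float = 0.05

    def is_masked(self, candidate: str, disease: str) -> bool:
        """Blank (non-significant) iff p_emp is strictly greater than the cutoff."""
        return self.cells[(candidate, disease)].p_emp > self.significance_cutoff

    def to_dataframe(self) -> pd.DataFrame:
        recs = []
        for c in self.rows:
            for d in self.cols:
                r = self.cells[(c, d)]
                recs.append({
                    "candidate": c, "disease": d,
                    "d_obs": r.d_obs, "p_emp": r.p_emp,
                    "p_display": r.p_display,
                    "z": np.nan if r.z_score is None else r.z_score,
                    "n_module_mapped": r.n_module_mapped,
                    "n_disease_mapped": r.n_disease_mapped,
                    "n_randomizations": r.n_randomizations,
                    "significant": not self.is_masked(c, d),
                })
        return pd.DataFrame.from_records(recs)

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False,
                                   float_format="%.6g")

    def to_heatmap(self, path) -> None:
        """p_emp heatmap with non-significant cells blanked."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        mat = np.full((len(self.rows), len(self.cols)), np.nan)
        for i, c in enumerate(self.rows):
            for j, d in enumerate(self.cols):
                if not self.is_masked(c, d):
                    mat[i, j] = self.cells[(c, d)].p_emp
        fig, ax = plt.subplots(
            figsize=(max(4, 0.6 * len(self.cols)), max(3, 0.6 * len(self.rows))))
        im = ax.imshow(mat, cmap="viridis_r",
                       vmin=0, vmax=self.significance_cutoff, aspect="auto")
        ax.set_xticks(range(len(self.cols)), self.cols, rotation=90)
        ax.set_yticks(range(len(self.rows)), self.rows)
        fig.colorbar(im, ax=ax, label="empirical p-value")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def _cell_seed(master: int, candidate: str, disease: str) -> np.random.Generator:
    # stable per-cell substream: crc32 is deterministic across runs/platforms
    ss = np.random.SeedSequence(
        [int(master), zlib.crc32(candidate.encode()), zlib.crc32(disease.encode())])
    return np.random.default_rng(ss)


def proximity_matrix(
    g: Interactome,
    modules: list[CandidateModule],
    diseases: list[GeneSet],
    n_randomizations: int = 250,
    rng_seed: int = 0,
    cutoff: float = 0.05,
    bins: DegreeBins | None = None,
    min_bin_size: int = 100,
) -> ProximityMatrix:
    """One proximity test per (candidate, disease) pair.

    Each cell runs on its own RNG substream derived from the master seed and
    the pair of labels, so the matrix is reproducible cell-by-cell and
    independent of evaluation order.
    """
    if not modules or not diseases:
        raise ValueError("modules and diseases must be non-empty")
    labels = [m.seed for m in modules]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate candidate labels")
    if bins is None:
        bins = build_degree_bins(g, min_bin_size=min_bin_size)
    cells = {}
    for m in modules:
        for dset in diseases:
            rng = _cell_seed(rng_seed, m.seed, dset.name)
            cells[(m.seed, dset.name)] = proximity_significance(
                g, m, dset, n_randomizations=n_randomizations,
                rng_seed=rng, bins=bins)
    return ProximityMatrix(rows=labels, cols=[d.name for d in diseases],
                           cells=cells, significance_cutoff=cutoff)
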