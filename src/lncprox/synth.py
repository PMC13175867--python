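"""Seeded synthetic data with truth labels for every pipeline stage.

Each generator is a pure function of its parameters (including the seed):
the same call reproduces inputs and truth exactly.  The generators emulate
the statistical structure the analyses assume -- a scale-free-like
interactome, a sense/antisense/beads pulldown with log-normal MS1
intensities, and a four-donor paired control/LPS expression design -- not
the physics of any instrument or the topology of any real network beyond
degree heavy-tails.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .interactome import GeneSet, Interactome, largest_connected_component
from .screen import CodingGene, ExpressionMatrix, TranscriptAnnotation

__all__ = [
    "SyntheticTruth",
    "gen_interactome",
    "plant_disease_gene_set",
    "gen_pulldown_dataset",
    "gen_expression_dataset",
    "gen_annotation_fixture",
]


@dataclass(frozen=True)
class SyntheticTruth:
    """What a generator planted, plus its full parameterization."""

    kind: str                      # proximity | pulldown | screen | annotation
    planted: dict
    parameters: dict

    def to_json(self, path) -> None:
        def default(o):
            if isinstance(o, (set, frozenset)):
                return sorted(o)
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            raise TypeError(type(o))
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2,
                      default=default, sort_keys=True)


def _symbolize(g: nx.Graph) -> nx.Graph:
    width = max(4, len(str(g.number_of_nodes())))
    mapping = {n: f"G{int(n):0{width}d}" for n in g.nodes}
    return nx.relabel_nodes(g, mapping)


def gen_interactome(n_nodes: int, model: str = "preferential_attachment",
                    model_params: dict | None = None, seed: int = 0
                    ) -> Interactome:
    """Random interactome restricted to its largest connected component.

    Models: preferential_attachment (m, default 3; heavy-tailed degrees),
    er (p), configuration (degree_sequence).
    """
    if n_nodes < 10:
        raise ValueError("n_nodes must be >= 10")
    params = dict(model_params or {})
    if model == "preferential_attachment":
        g = nx.barabasi_albert_graph(n_nodes, params.get("m", 3), seed=seed)
    elif model == "er":
        g = nx.gnp_random_graph(n_nodes, params.get("p", 0.01), seed=seed)
    elif model == "configuration":
        seq = params["degree_sequence"]
        g = nx.configuration_model(seq, seed=seed)
        g = nx.Graph(g)  # collapse multi-edges
        g.remove_edges_from(nx.selfloop_edges(g))
    else:
        raise ValueError(f"unknown model {model!r}")
    if g.number_of_nodes() == 0 or g.number_of_edges() == 0:
        raise ValueError("generated graph is empty; adjust model parameters")
    inter = Interactome.from_nx(_symbolize(g), name=f"synthetic-{model}")
    return largest_connected_component(inter)


def pick_candidate(g: Interactome, target_degree: int = 10) -> str:
    """Deterministically pick a moderate-degree candidate seed.

    Modules of the very highest-degree hubs are closer to *any* gene set
    than their degree-matched nulls (their neighbors are more central than
    bin-mates of equal degree), which confounds planting experiments; a
    moderate-degree candidate keeps the null well behaved so that planted
    proximity, not candidate centrality, drives significance.
    """
    return min(sorted(g.nodes),
               key=lambda n: (abs(g.degree(n) - target_degree), n))


def plant_disease_gene_set(g: Interactome, candidate_seed: str, size: int,
                           closeness: float, seed: int = 0,
                           name: str = "planted_disease"
                           ) -> tuple[GeneSet, SyntheticTruth]:
    """Sample a disease gene set biased toward the candidate module.

    Genes are drawn without replacement with weight exp(-closeness * d),
    where d is the shortest-path distance to the candidate module (seed plus
    first neighbors; 0 inside the module).  closeness = 0 is the uniform
    null; large closeness concentrates the set in and around the module.
    """
    if candidate_seed not in g:
        raise KeyError(f"candidate seed {candidate_seed!r} not in graph")
    if closeness < 0:
        raise ValueError("closeness must be >= 0")
    nodes = sorted(g.nodes)
    if size >= len(nodes):
        raise ValueError(f"size={size} infeasible for {len(nodes)} nodes")
    module = g.neighbors(candidate_seed) | {candidate_seed}
    dist = nx.multi_source_dijkstra_path_length(g.graph, module)
    rng = np.random.default_rng(seed)
    d = np.array([dist[n] for n in nodes], dtype=float)
    w = np.exp(-closeness * d)
    members = rng.choice(nodes, size=size, replace=False, p=w / w.sum())
    gene_set = GeneSet(name, frozenset(members.tolist()))
    truth = SyntheticTruth(
        kind="proximity",
        planted={"disease_genes": set(gene_set.members),
                 "candidate_seed": candidate_seed},
        parameters={"size": size, "closeness": closeness, "seed": seed,
                    "n_nodes": len(nodes)})
    return gene_set, truth


def gen_pulldown_dataset(n_proteins: int = 200, n_planted: int = 3,
                         enrichment_fold: float = 4.0, n_experiments: int = 3,
                         seed: int = 0, n_decoys: int = 5,
                         noise_log2_sd: float = 0.2
                         ) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Peptide table for a sense/antisense/beads pulldown with planted interactors.

    Background proteins carry 2-8 unique peptides whose log-normal base AUCs
    are shared across conditions, perturbed by per-observation log-normal
    noise, so their expected enrichment is 1.  Planted interactors have all
    sense AUCs multiplied by ``enrichment_fold``.  Decoy proteins carry a
    single unique peptide with strong (100-fold) sense enrichment; the
    two-unique-peptides rule must keep them out of every call.  A handful of
    non-unique (shared) peptide rows are included and must be ignored.
    """
    if n_planted >= n_proteins:
        raise ValueError("n_planted must be < n_proteins")
    if enrichment_fold < 1:
        raise ValueError("enrichment_fold must be >= 1")
    rng = np.random.default_rng(seed)
    proteins = [f"P{i:04d}" for i in range(n_proteins)]
    planted = set(rng.choice(proteins, size=n_planted, replace=False).tolist())
    rows = []
    for p_i, prot in enumerate(proteins):
        n_pep = int(rng.integers(2, 9))
        base = rng.lognormal(mean=13.0, sigma=1.2, size=n_pep)
        for exp_i in range(1, n_experiments + 1):
            for cond in ("S", "AS", "B"):
                noise = np.exp2(rng.normal(0.0, noise_log2_sd, size=n_pep))
                auc = base * noise
                if prot in planted and cond == "S":
                    auc = auc * enrichment_fold
                for k in range(n_pep):
                    rows.append((f"exp{exp_i}", cond, prot,
                                 f"{prot}_pep{k}", True, auc[k]))
    # single-unique-peptide decoys with huge sense enrichment: never callable
    decoys = [f"DECOY{i:02d}" for i in range(n_decoys)]
    for prot in decoys:
        base = float(rng.lognormal(mean=13.0, sigma=1.2))
        for exp_i in range(1, n_experiments + 1):
            for cond in ("S", "AS", "B"):
                auc = base * (100.0 if cond == "S" else 1.0)
                rows.append((f"exp{exp_i}", cond, prot, f"{prot}_pep0",
                             True, auc))
    # shared (non-unique) peptides attached to background proteins: ignored
    for prot in proteins[: min(3, n_proteins)]:
        for exp_i in range(1, n_experiments + 1):
            for cond in ("S", "AS", "B"):
                rows.append((f"exp{exp_i}", cond, prot, "SHAREDPEPTIDE",
                             False, float(rng.lognormal(13.0, 1.2))))
    df = pd.DataFrame(rows, columns=["experiment", "condition", "protein",
                                     "peptide", "is_unique", "auc"])
    truth = SyntheticTruth(
        kind="pulldown",
        planted={"interactors": planted, "decoys": set(decoys)},
        parameters={"n_proteins": n_proteins, "n_planted": n_planted,
                    "enrichment_fold": enrichment_fold,
                    "n_experiments": n_experiments, "seed": seed,
                    "n_decoys": n_decoys, "noise_log2_sd": noise_log2_sd})
    return df, truth


def gen_expression_dataset(n_transcripts: int = 1000, n_donors: int = 4,
                           n_planted: int = 50, log2_effect: float = 2.0,
                           noise_sd: float = 0.25, donor_sd: float = 0.3,
                           seed: int = 0
                           ) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Paired control/LPS expression matrix with planted up-regulated transcripts.

    Per transcript: baseline log2 intensity ~ Normal(8, 1.5); a per
    (transcript, donor) random effect with sd ``donor_sd`` shared by both
    conditions of a donor (it cancels in paired differences); i.i.d. log2
    noise with sd ``noise_sd``; planted transcripts gain ``log2_effect`` in
    the LPS samples.  The returned matrix is linear-scale.
    """
    if n_planted > n_transcripts:
        raise ValueError("n_planted must be <= n_transcripts")
    rng = np.random.default_rng(seed)
    transcripts = [f"LNC{i:05d}" for i in range(n_transcripts)]
    planted = set(rng.choice(transcripts, size=n_planted,
                             replace=False).tolist()) if n_planted else set()
    base = rng.normal(8.0, 1.5, size=n_transcripts)
    effect = np.array([log2_effect if t in planted else 0.0
                       for t in transcripts])
    cols, data = [], []
    for d_i in range(1, n_donors + 1):
        donor_eff = rng.normal(0.0, donor_sd, size=n_transcripts)
        for cond in ("control", "LPS"):
            log2x = (base + donor_eff
                     + (effect if cond == "LPS" else 0.0)
                     + rng.normal(0.0, noise_sd, size=n_transcripts))
            cols.append(f"D{d_i}_{cond}")
            data.append(np.exp2(log2x))
    values = pd.DataFrame(np.column_stack(data), index=transcripts,
                          columns=cols)
    design = pd.DataFrame({
        "sample": cols,
        "donor": [c.split("_")[0] for c in cols],
        "condition": [c.split("_")[1] for c in cols],
    })
    matrix = ExpressionMatrix(values=values, design=design)
    truth = SyntheticTruth(
        kind="screen",
        planted={"up_regulated": planted},
        parameters={"n_transcripts": n_transcripts, "n_donors": n_donors,
                    "n_planted": n_planted, "log2_effect": log2_effect,
                    "noise_sd": noise_sd, "donor_sd": donor_sd, "seed": seed})
    return matrix, truth


def gen_annotation_fixture(seed: int = 0, n_intergenic: int = 7,
                           n_antisense: int = 2, n_intron_sense: int = 1,
                           n_exon_sense: int = 1
                           ) -> tuple[list[TranscriptAnnotation],
                                      list[CodingGene], SyntheticTruth]:
    """One toy chromosome exercising all four positional lncRNA classes.

    The default composition (7 intergenic, 2 antisense, 1 intron-sense
    overlapping, 1 exon-sense overlapping) mirrors a typical LPS-screen hit
    list.  The seed jitters coordinates without changing any class.
    """
    rng = np.random.default_rng(seed)
    chrom = "chrT"
    genes: list[CodingGene] = []
    lncs: list[TranscriptAnnotation] = []
    truth_labels: dict[str, str] = {}
    cursor = 1000
    block = 50_000  # one gene locus plus flanking space per block

    def jitter(hi=200):
        return int(rng.integers(0, hi))

    n_loci = n_antisense + n_intron_sense + n_exon_sense
    kinds = (["antisense"] * n_antisense
             + ["intron-sense overlapping"] * n_intron_sense
             + ["exon-sense overlapping"] * n_exon_sense)
    for i, kind in enumerate(kinds):
        gstart = cursor + jitter()
        gend = gstart + 20_000
        exon1 = (gstart, gstart + 2_000)
        exon2 = (gend - 2_000, gend)
        gene = CodingGene(name=f"GENE{i:02d}", chrom=chrom, start=gstart,
                          end=gend, strand="+", exons=(exon1, exon2))
        genes.append(gene)
        lname = f"LNC_{kind.split()[0].upper().replace('-', '_')}{i:02d}"
        if kind == "antisense":
            l = TranscriptAnnotation(lname, chrom, gstart + 5_000 + jitter(),
                                     gstart + 9_000, "-")
        elif kind == "intron-sense overlapping":
            l = TranscriptAnnotation(lname, chrom, exon1[1] + 500 + jitter(),
                                     exon2[0] - 500, "+")
        else:  # exon-sense overlapping
            l = TranscriptAnnotation(lname, chrom, gstart + 500 + jitter(500),
                                     gstart + 6_000, "+")
        lncs.append(l)
        truth_labels[lname] = kind
        cursor += block
    for i in range(n_intergenic):
        start = cursor + jitter()
        l = TranscriptAnnotation(f"LNC_INTERGENIC{i:02d}", chrom, start,
                                 start + 3_000, "+" if i % 2 == 0 else "-")
        lncs.append(l)
        truth_labels[l.name] = "intergenic"
        cursor += 10_000
    truth = SyntheticTruth(
        kind="annotation",
        planted={"classes": truth_labels},
        parameters={"seed": seed, "n_intergenic": n_intergenic,
                    "n_antisense": n_antisense,
                    "n_intron_sense": n_intron_sense,
                    "n_exon_sense": n_exon_sense, "n_gene_loci": n_loci})
    return lncs, genes, truth


def write_annotation_fixture(lncs, genes, bed_path, gff3_path) -> None:
    """Write lncRNAs as BED6 and coding genes (with exons) as GFF3."""
    with open(bed_path, "w") as fh:
        for l in lncs:
            fh.write(f"{l.chrom}\t{l.start}\t{l.end}\t{l.name}\t0\t{l.strand}\n")
    with open(gff3_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(f"{g.chrom}\tsynthetic\tgene\t{g.start + 1}\t{g.end}\t."
                     f"\t{g.strand}\t.\tID={g.name}\n")
            for j, (s, e) in enumerate(g.exons):
                fh.write(f"{g.chrom}\tsynthetic\texon\t{s + 1}\t{e}\t."
                         f"\t{g.strand}\t.\tID={g.name}.exon{j};Parent={g.name}\n")
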