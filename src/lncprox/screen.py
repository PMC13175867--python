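"""Paired LPS-response expression screen with a moderated t statistic.

The design is paired: each donor contributes one control and one LPS sample.
Per transcript, the paired log2 differences d_i = log2(LPS_i) - log2(ctrl_i)
are tested against zero with an empirical-Bayes moderated t: the residual
variance s^2 of each transcript is shrunk toward a global prior variance
s0^2 with prior degrees of freedom d0,

    s_tilde^2 = (d0 * s0^2 + (n-1) * s^2) / (d0 + n - 1),
    t = mean(d) / (s_tilde / sqrt(n)),   df = (n - 1) + d0,

where (d0, s0^2) are estimated across all transcripts by method of moments
on log s^2 (a scaled chi-square fit, as in empirical-Bayes linear-model
practice).  P-values are Benjamini-Hochberg adjusted, and hits satisfy
q < 0.05 with linear fold change >= 2 (screening for up-regulation by
default).

Row Z-scores (subtract the row mean, divide by the sample standard
deviation) are provided for heatmap display, and hits are classified by
genomic position relative to coding genes: intergenic, antisense,
intron-sense overlapping, or exon-sense overlapping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "TranscriptAnnotation",
    "CodingGene",
    "paired_moderated_test",
    "bh_adjust",
    "apply_screen_filter",
    "zscore_rows",
    "classify_lncrna_position",
    "classify_table",
    "read_design",
    "read_expression_matrix",
    "read_transcript_bed",
    "read_coding_genes_gff3",
]

POSITIONAL_CLASSES = ("intergenic", "antisense", "intron-sense overlapping",
                      "exon-sense overlapping", "unclassified")


@dataclass
class ExpressionMatrix:
    """Linear-scale transcripts x samples matrix plus the paired design.

    ``values``: DataFrame indexed by transcript, columns are sample labels.
    ``design``: DataFrame with columns sample, donor, condition where
    condition is 'control' or 'LPS'; every donor must contribute exactly
    one sample of each condition.
    """

    values: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self):
        d = self.design
        required = {"sample", "donor", "condition"}
        if not required <= set(d.columns):
            raise ValueError(f"design needs columns {sorted(required)}")
        bad = set(d["condition"]) - {"control", "LPS"}
        if bad:
            raise ValueError(f"unknown condition(s): {sorted(bad)}")
        if set(d["sample"]) != set(self.values.columns):
            raise ValueError("design samples do not match matrix columns")
        for donor, grp in d.groupby("donor"):
            conds = sorted(grp["condition"])
            if conds != ["LPS", "control"]:
                raise ValueError(
                    f"donor {donor!r} must have exactly one control and one "
                    f"LPS sample, got {conds}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")

    @property
    def donors(self) -> list[str]:
        return sorted(self.design["donor"].unique())

    def paired_columns(self) -> list[tuple[str, str]]:
        """(control, LPS) sample label per donor, donor-sorted."""
        out = []
        for donor in self.donors:
            grp = self.design[self.design["donor"] == donor]
            ctrl = grp.loc[grp["condition"] == "control", "sample"].iloc[0]
            lps = grp.loc[grp["condition"] == "LPS", "sample"].iloc[0]
            out.append((ctrl, lps))
        return out


def read_expression_matrix(matrix_path, design_path) -> ExpressionMatrix:
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    design = read_design(design_path)
    return ExpressionMatrix(values=values, design=design)


def read_design(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (monotone decreasing)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(75):
        tri = special.polygamma(1, x)
        step = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += step
        if abs(step) < 1e-10 * x:
            break
    return float(x)


def _fit_log_variance_prior(s2: np.ndarray, df: int) -> tuple[float, float]:
    """Method-of-moments fit of (d0, s0^2) from log residual variances.

    Under s^2 ~ s0^2 * F(df, d0), log s^2 has mean
    log s0^2 + psi(df/2) - log(df/2) - psi(d0/2) + log(d0/2)
    and variance trigamma(df/2) + trigamma(d0/2); the moments across
    transcripts identify the prior.  Zero variances are excluded from the
    fit but still moderated.  Returns (d0, s0_sq); d0 = inf when the
    observed spread is no wider than pure chi-square noise.
    """
    pos = s2[s2 > 0]
    if pos.size < 2:
        return np.inf, float(pos.mean()) if pos.size else 0.0
    z = np.log(pos)
    e_mean = float(z.mean())
    e_var = float(z.var(ddof=1))
    noise = float(special.polygamma(1, df / 2.0))
    excess = e_var - noise
    if excess <= 0:
        d0 = np.inf
        log_s0 = e_mean - special.polygamma(0, df / 2.0) + np.log(df / 2.0)
    else:
        d0 = 2.0 * _trigamma_inverse(excess)
        log_s0 = (e_mean - special.polygamma(0, df / 2.0) + np.log(df / 2.0)
                  + special.polygamma(0, d0 / 2.0) - np.log(d0 / 2.0))
    return float(d0), float(np.exp(log_s0))


def paired_moderated_test(m: ExpressionMatrix, prior_df: float | None = None,
                          log_offset: float = 1.0) -> pd.DataFrame:
    """Per-transcript moderated paired t-test of LPS vs control.

    Returns a DataFrame with columns transcript, mean_log2fc, fc_linear,
    t_stat, p (plus the fitted prior in ``attrs``).  ``prior_df`` overrides
    the estimated d0 when given.  A ``log_offset`` is added before log2 only
    when the matrix contains zeros.
    """
    pairs = m.paired_columns()
    n = len(pairs)
    if n < 2:
        raise ValueError("need at least 2 donors for a paired test")
    vals = m.values.to_numpy(dtype=float)
    offset = log_offset if (vals == 0).any() else 0.0
    logv = np.log2(vals + offset)
    cols = list(m.values.columns)
    idx = {c: i for i, c in enumerate(cols)}
    d = np.stack([logv[:, idx[lps]] - logv[:, idx[ctrl]]
                  for ctrl, lps in pairs], axis=1)  # transcripts x donors

    mean_d = d.mean(axis=1)
    s2 = d.var(axis=1, ddof=1)
    df_resid = n - 1

    if prior_df is None:
        d0, s0_sq = _fit_log_variance_prior(s2, df_resid)
    else:
        d0 = float(prior_df)
        s0_sq = float(np.median(s2))

    if np.isinf(d0):
        s2_mod = np.full_like(s2, s0_sq)
        df_total = 1e7  # effectively normal reference
    else:
        s2_mod = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
        df_total = df_resid + d0

    se = np.sqrt(s2_mod / n)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, mean_d / np.where(se > 0, se, 1.0),
                     np.where(mean_d == 0, 0.0, np.sign(mean_d) * np.inf))
    p = 2.0 * stats.t.sf(np.abs(t), df=df_total)
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    out = pd.DataFrame({
        "transcript": m.values.index,
        "mean_log2fc": mean_d,
        "fc_linear": np.exp2(mean_d),
        "t_stat": t,
        "p": p,
    })
    out.attrs["prior_df"] = d0
    out.attrs["prior_var"] = s0_sq
    out.attrs["n_donors"] = n
    return out


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def apply_screen_filter(rows: pd.DataFrame, fdr_cutoff: float = 0.05,
                        fc_cutoff: float = 2.0, direction: str = "up"
                        ) -> pd.DataFrame:
    """Set the ``hit`` flag: q strictly below the FDR cutoff AND fold change
    at or above the cutoff (boundary FC included, boundary q excluded)."""
    if direction not in ("up", "both"):
        raise ValueError("direction must be 'up' or 'both'")
    out = rows.copy()
    if "q" not in out.columns:
        out["q"] = bh_adjust(out["p"].to_numpy())
    fc = out["fc_linear"].to_numpy(dtype=float)
    eff_fc = fc if direction == "up" else np.maximum(fc, 1.0 / fc)
    out["hit"] = (out["q"].to_numpy() < fdr_cutoff) & (eff_fc >= fc_cutoff)
    return out


def zscore_rows(values: pd.DataFrame) -> tuple[pd.DataFrame, list]:
    """Row-standardize for heatmap display; constant rows become zero and
    are returned in the flagged list."""
    if values.shape[1] < 2:
        raise ValueError("row Z-scores need at least 2 samples")
    x = values.to_numpy(dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    flagged = values.index[(sd == 0).ravel()].tolist()
    if flagged:
        logger.info("zscore_rows: %d constant row(s) set to zero", len(flagged))
    safe = np.where(sd == 0, 1.0, sd)
    z = np.where(sd == 0, 0.0, (x - mu) / safe)
    return pd.DataFrame(z, index=values.index, columns=values.columns), flagged


# --------------------------------------------------------------------------
# positional classification of lncRNAs relative to coding genes
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TranscriptAnnotation:
    """0-based half-open genomic interval of one transcript."""

    name: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"{self.name}: invalid interval "
                             f"[{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.name}: strand must be + or -")


@dataclass(frozen=True)
class CodingGene:
    name: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...] = field(default=())

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"{self.name}: invalid interval")
        for s, e in self.exons:
            if not (self.start <= s < e <= self.end):
                raise ValueError(f"{self.name}: exon [{s},{e}) outside gene bounds")


def _overlaps(a_start, a_end, b_start, b_end) -> bool:
    return a_start < b_end and b_start < a_end


def classify_lncrna_position(lnc: TranscriptAnnotation,
                             coding: list[CodingGene]) -> str:
    """Four-way positional class of a lncRNA relative to coding genes.

    No genomic overlap with any coding gene -> intergenic.  Same-strand
    overlap takes precedence over antisense: touching any coding exon makes
    it exon-sense overlapping, otherwise intron-sense overlapping.  Overlap
    with opposite-strand genes only -> antisense.
    """
    same, opposite = [], []
    for gene in coding:
        if gene.chrom != lnc.chrom:
            continue
        if not _overlaps(lnc.start, lnc.end, gene.start, gene.end):
            continue
        (same if gene.strand == lnc.strand else opposite).append(gene)
    if not same and not opposite:
        return "intergenic"
    if same:
        for gene in same:
            if any(_overlaps(lnc.start, lnc.end, s, e) for s, e in gene.exons):
                return "exon-sense overlapping"
        return "intron-sense overlapping"
    return "antisense"


def classify_table(lncs: list[TranscriptAnnotation],
                   coding: list[CodingGene]) -> pd.DataFrame:
    return pd.DataFrame({
        "transcript": [l.name for l in lncs],
        "positional_class": [classify_lncrna_position(l, coding) for l in lncs],
    })


def read_transcript_bed(path) -> list[TranscriptAnnotation]:
    """BED (>= 6 columns) transcript intervals, 0-based half-open."""
    import pyranges as pr

    df = pr.read_bed(str(path), as_df=True)
    if "Strand" not in df.columns or "Name" not in df.columns:
        raise ValueError(f"{path}: need BED6+ with name and strand")
    return [TranscriptAnnotation(name=r.Name, chrom=str(r.Chromosome),
                                 start=int(r.Start), end=int(r.End),
                                 strand=str(r.Strand))
            for r in df.itertuples()]


def read_coding_genes_gff3(path) -> list[CodingGene]:
    """Coding genes with exons from GFF3 (1-based closed, converted to
    0-based half-open).  Exons are attached to their gene via the ID/Parent
    attributes; exon parents may be the gene itself or an mRNA child."""
    import pyranges as pr

    df = pr.read_gff3(str(path), as_df=True)
    genes = df[df.Feature == "gene"]
    parent_to_gene: dict[str, str] = {}
    for r in genes.itertuples():
        parent_to_gene[r.ID] = r.ID
    if "Parent" in df.columns:
        for r in df[df.Feature == "mRNA"].itertuples():
            parent_to_gene[r.ID] = parent_to_gene.get(r.Parent, r.Parent)
    exons: dict[str, list[tuple[int, int]]] = {}
    exon_rows = df[df.Feature == "exon"]
    for r in exon_rows.itertuples():
        gid = parent_to_gene.get(r.Parent, r.Parent)
        exons.setdefault(gid, []).append((int(r.Start), int(r.End)))
    out = []
    for r in genes.itertuples():
        out.append(CodingGene(
            name=r.ID, chrom=str(r.Chromosome), start=int(r.Start),
            end=int(r.End), strand=str(r.Strand),
            exons=tuple(sorted(exons.get(r.ID, [])))))
    return out
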