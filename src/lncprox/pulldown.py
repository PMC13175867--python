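"""RNA-pulldown interactor calling from peptide-level MS1 abundances.

Input is a post-search peptide table (one row per peptide observation) with
three conditions per experiment: sense RNA bait (S), antisense control (AS)
and beads-only control (B).  Only peptides unique to one protein group are
quantified.  Per (experiment, condition, protein):

* duplicate rows of the same peptide sequence are summed first (they are
  redundant observations of one peptide species),
* proteins with fewer than two distinct unique peptides are dropped,
* protein abundance is the mean MS1 AUC of the top three (or fewer) most
  abundant unique peptides.

A protein is called an interactor within an experiment when its abundance
shows more than two-fold enrichment in sense over antisense (S/AS) AND in
sense over beads (S/B); the boundary ratio 2.0 fails.  A protein absent (or
zero) in a control is maximal evidence of sense-specific binding, so the
ratio is +inf unless a pseudo-count floor is requested.  The final call
intersects per-experiment pass sets across replicate experiments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .interactome import GeneSet

__all__ = [
    "CONDITIONS",
    "PeptideRecord",
    "rollup_protein_abundance",
    "compute_enrichment_ratios",
    "intersect_experiments",
    "call_interactors",
]

CONDITIONS = ("S", "AS", "B")

PEPTIDE_COLUMNS = ["experiment", "condition", "protein", "peptide",
                   "is_unique", "auc"]


@dataclass(frozen=True)
class PeptideRecord:
    experiment: str
    condition: str
    protein: str
    peptide: str
    is_unique: bool
    auc: float


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame([r.__dict__ for r in records])
    missing = set(PEPTIDE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"peptide table missing columns: {sorted(missing)}")
    if df.empty:
        raise ValueError("empty peptide table")
    df["is_unique"] = df["is_unique"].map(
        lambda v: str(v).strip().lower() in ("1", "true", "t", "yes"))
    df["auc"] = df["auc"].astype(float)
    bad = df.index[df["auc"] < 0]
    if len(bad):
        row = df.loc[bad[0]]
        raise ValueError(
            f"negative AUC for peptide {row['peptide']!r} of protein "
            f"{row['protein']!r} ({row['experiment']}/{row['condition']})")
    bad_cond = set(df["condition"]) - set(CONDITIONS)
    if bad_cond:
        raise ValueError(f"unknown condition label(s): {sorted(bad_cond)}")
    return df


def rollup_protein_abundance(records, top_n: int = 3, min_unique: int = 2,
                             stat: str = "mean") -> pd.DataFrame:
    """Roll peptide AUCs up to protein abundances per (experiment, condition).

    Returns a DataFrame with columns experiment, condition, protein,
    n_unique_peptides, abundance.  ``stat`` selects mean (default) or sum of
    the top-``top_n`` peptide AUCs.
    """
    if stat not in ("mean", "sum"):
        raise ValueError("stat must be 'mean' or 'sum'")
    df = _as_frame(records)
    df = df[df["is_unique"]]
    if df.empty:
        return pd.DataFrame(columns=["experiment", "condition", "protein",
                                     "n_unique_peptides", "abundance"])
    # collapse duplicate rows of one peptide species before ranking
    pep = (df.groupby(["experiment", "condition", "protein", "peptide"],
                      sort=False)["auc"].sum().reset_index())

    def _cell(aucs: pd.Series):
        top = np.sort(aucs.to_numpy())[::-1][:top_n]
        return top.mean() if stat == "mean" else top.sum()

    grp = pep.groupby(["experiment", "condition", "protein"], sort=False)["auc"]
    out = grp.agg(n_unique_peptides="size", abundance=_cell).reset_index()
    out = out[out["n_unique_peptides"] >= min_unique].reset_index(drop=True)
    return out


def compute_enrichment_ratios(abundances: pd.DataFrame, experiment: str,
                              fold: float = 2.0, floor: float = 0.0
                              ) -> pd.DataFrame:
    """S/AS and S/B enrichment calls for one experiment.

    Only proteins quantified in the sense condition are candidates.  A
    missing or zero control abundance yields a ratio of +inf (or S/floor
    when a positive pseudo-count floor is given).  ``passes`` requires both
    ratios strictly above ``fold``.
    """
    sub = abundances[abundances["experiment"] == experiment]
    sense = sub[sub["condition"] == "S"].set_index("protein")["abundance"]
    if sense.empty:
        raise ValueError(f"experiment {experiment!r} has no sense-condition proteins")
    controls = {
        cond: sub[sub["condition"] == cond].set_index("protein")["abundance"]
        for cond in ("AS", "B")
    }

    def ratio(s_val: float, ctrl: pd.Series, protein: str) -> float:
        denom = max(float(ctrl.get(protein, 0.0)), floor)
        if denom <= 0:
            return math.inf
        return s_val / denom

    recs = []
    for protein, s_val in sense.items():
        r_as = ratio(s_val, controls["AS"], protein)
        r_b = ratio(s_val, controls["B"], protein)
        recs.append({
            "experiment": experiment, "protein": protein,
            "ratio_s_as": r_as, "ratio_s_b": r_b,
            "passes": bool(r_as > fold and r_b > fold),
        })
    return pd.DataFrame.from_records(recs)


def intersect_experiments(calls: list[pd.DataFrame], mode: str = "all",
                          k: int | None = None, name: str = "interactors"
                          ) -> tuple[GeneSet, dict[str, int]]:
    """Intersect per-experiment pass sets (Venn logic across replicates).

    mode='all' keeps proteins passing in every experiment; mode='at_least_k'
    keeps those passing in >= k.  Also returns per-experiment pass counts
    for Venn reporting.
    """
    if not calls:
        raise ValueError("need at least one experiment")
    pass_sets = []
    counts: dict[str, int] = {}
    for df in calls:
        exps = set(df["experiment"])
        if len(exps) != 1:
            raise ValueError("each call table must hold exactly one experiment")
        exp = exps.pop()
        passed = set(df.loc[df["passes"], "protein"])
        pass_sets.append(passed)
        counts[exp] = len(passed)
    if mode == "all":
        k = len(pass_sets)
    elif mode == "at_least_k":
        if k is None or k < 1 or k > len(pass_sets):
            raise ValueError(f"k must be in 1..{len(pass_sets)}")
    else:
        raise ValueError(f"unknown mode {mode!r}")
    tally: dict[str, int] = {}
    for s in pass_sets:
        for p in s:
            tally[p] = tally.get(p, 0) + 1
    final = {p for p, c in tally.items() if c >= k}
    if not final:
        # GeneSet forbids empty sets; callers get the counts and an empty frozenset
        return None, counts
    return GeneSet(name, frozenset(final)), counts


def call_interactors(records, mode: str = "all", k: int | None = None,
                     fold: float = 2.0, floor: float = 0.0,
                     top_n: int = 3, min_unique: int = 2,
                     stat: str = "mean") -> tuple[set[str], pd.DataFrame]:
    """Full cascade: rollup -> per-experiment enrichment -> intersection.

    Returns the called interactor set and the per-experiment call table.
    """
    abund = rollup_protein_abundance(records, top_n=top_n,
                                     min_unique=min_unique, stat=stat)
    experiments = sorted(abund["experiment"].unique())
    calls = [compute_enrichment_ratios(abund, e, fold=fold, floor=floor)
             for e in experiments]
    gene_set, _counts = intersect_experiments(calls, mode=mode, k=k)
    table = pd.concat(calls, ignore_index=True) if calls else pd.DataFrame()
    return (set() if gene_set is None else set(gene_set.members)), table
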