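"""Three-way expression/proteomic validation of predicted genes.

A predicted protein-coding gene counts as validated by:

* the Transcriptome Method — >= 60% of its genomic span covered by a
  transcript that maps uniquely to its locus;
* the FPKM Method — RNA expression strictly greater than 1 FPKM
  (fragments per kilobase of transcript per million mapped fragments)
  in at least one experimental condition;
* the Protein Method — at least one peptide below the q-value cutoff
  (default 0.01) that is an exact substring of exactly one predicted
  protein, that protein being the gene's product.

Genes are then partitioned by their evidence combination (the Venn
cells), and the association between the "dubious" annotation label and
validation is tested with a two-sided Fisher exact test computed
entirely in log space, so astronomically small p-values (the original
application reports P < 1e-195) remain finite and exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

FLAG_COLUMNS = ["transcriptome_flag", "fpkm_flag", "protein_flag"]
VENN_CELLS = ["TFP", "TF", "TP", "FP", "T", "F", "P", "none"]


@dataclass
class ValidationThresholds:
    """Cutoffs for the three validation methods."""

    transcript_overlap_min: float = 0.60   # inclusive ("at least 60%")
    fpkm_min: float = 1.0                  # strict ("greater than 1")
    peptide_q_max: float = 0.01            # strict ("FDR < 0.01")

    def __post_init__(self) -> None:
        if not (0 < self.transcript_overlap_min <= 1):
            raise ValueError("transcript_overlap_min must be in (0, 1]")
        if self.fpkm_min < 0 or not (0 < self.peptide_q_max <= 1):
            raise ValueError("bad FPKM or q-value threshold")


DEFAULT_THRESHOLDS = ValidationThresholds()


def compute_fpkm(count: float, gene_length: int, library_total: float) -> float:
    """FPKM = count * 1e9 / (gene_length * library_total)."""
    if gene_length <= 0 or library_total <= 0:
        raise ValueError("gene_length and library_total must be positive")
    return count * 1e9 / (gene_length * library_total)


def fpkm_table(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-gene, per-condition FPKM from a long count table.

    ``counts`` needs columns gene_id, condition, count, gene_length;
    the per-condition library size is the condition's total mapped
    count.
    """
    totals = counts.groupby("condition")["count"].transform("sum")
    out = counts.copy()
    out["fpkm"] = out["count"] * 1e9 / (out["gene_length"] * totals)
    return out


def fpkm_validate(
    gene_id: str,
    fpkms: pd.DataFrame,
    thresholds: ValidationThresholds = DEFAULT_THRESHOLDS,
) -> bool:
    """True iff the gene's FPKM exceeds the cutoff (strictly) in at
    least one condition."""
    rows = fpkms.loc[fpkms["gene_id"] == gene_id, "fpkm"]
    return bool((rows > thresholds.fpkm_min).any())


def transcript_overlap_validate(
    gene_id: str,
    alignments: pd.DataFrame,
    thresholds: ValidationThresholds = DEFAULT_THRESHOLDS,
) -> bool:
    """True iff a uniquely-mapped transcript (n_loci == 1) covers at
    least the cutoff fraction of the gene's genomic span (inclusive)."""
    rows = alignments[(alignments["gene_id"] == gene_id) & (alignments["n_loci"] == 1)]
    return bool((rows["covered_fraction"] >= thresholds.transcript_overlap_min).any())


def peptide_validate(
    gene_id: str,
    peptides: pd.DataFrame,
    proteome: dict[str, str],
    thresholds: ValidationThresholds = DEFAULT_THRESHOLDS,
) -> bool:
    """True iff some peptide with q below the cutoff is an exact
    substring of exactly one predicted protein, and that protein is the
    gene's product.  Ambiguous peptides (matching two or more proteins)
    contribute to no gene."""
    target = proteome.get(gene_id)
    if target is None:
        return False
    good = peptides[peptides["q_value"] < thresholds.peptide_q_max]
    for pep in good["peptide"].unique():
        owners = [pid for pid, prot in proteome.items() if pep in prot]
        if owners == [gene_id]:
            return True
    return False


def build_evidence_set(
    gene_ids: list[str],
    alignments: pd.DataFrame,
    counts: pd.DataFrame,
    peptides: pd.DataFrame,
    proteome: dict[str, str],
    dubious: set[str] | None = None,
    repeats: set[str] | None = None,
    non_reference: set[str] | None = None,
    thresholds: ValidationThresholds = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Per-gene boolean evidence flags from the three methods plus the
    dubious / repeat / non-reference input labels."""
    dubious = dubious or set()
    repeats = repeats or set()
    non_reference = non_reference or set()
    fpkms = fpkm_table(counts)

    # precompute unambiguous peptide -> owner mapping once
    good = peptides[peptides["q_value"] < thresholds.peptide_q_max]
    peptide_owner: dict[str, str | None] = {}
    for pep in good["peptide"].unique():
        owners = [pid for pid, prot in proteome.items() if pep in prot]
        peptide_owner[pep] = owners[0] if len(owners) == 1 else None
    protein_hit = {owner for owner in peptide_owner.values() if owner is not None}

    uniq = alignments[alignments["n_loci"] == 1]
    covered = set(
        uniq.loc[uniq["covered_fraction"] >= thresholds.transcript_overlap_min, "gene_id"]
    )
    expressed = set(fpkms.loc[fpkms["fpkm"] > thresholds.fpkm_min, "gene_id"])

    rows = []
    for gid in gene_ids:
        rows.append(
            {
                "gene_id": gid,
                "transcriptome_flag": gid in covered,
                "fpkm_flag": gid in expressed,
                "protein_flag": gid in protein_hit and gid in proteome,
                "dubious_flag": gid in dubious,
                "repeat_flag": gid in repeats,
                "non_reference_flag": gid in non_reference,
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


def venn_partition(
    evidence: pd.DataFrame,
    selector: pd.Series | None = None,
) -> dict[str, int]:
    """Counts per evidence combination over a gene subset.

    Cells are labelled by the methods present: T (transcriptome),
    F (FPKM), P (protein); the eight cells plus ``total`` and
    ``no_evidence`` are returned, and the cells partition the subset
    exactly.
    """
    sub = evidence if selector is None else evidence[selector.reindex(evidence.index)]
    out = {cell: 0 for cell in VENN_CELLS}
    for t, f, p in sub[FLAG_COLUMNS].itertuples(index=False):
        label = ("T" if t else "") + ("F" if f else "") + ("P" if p else "")
        out[label or "none"] += 1
    out["total"] = len(sub)
    out["no_evidence"] = out["none"]
    return out


STANDARD_SELECTORS = {
    "all": lambda ev: pd.Series(True, index=ev.index),
    "nondubious": lambda ev: ~ev["dubious_flag"],
    "non_reference": lambda ev: ev["non_reference_flag"],
    "non_reference_norepeat": lambda ev: ev["non_reference_flag"] & ~ev["repeat_flag"],
}


def dubious_contingency(evidence: pd.DataFrame, method: str = "protein_flag") -> np.ndarray:
    """2x2 table of (nondubious, dubious) x (validated, not) for one method."""
    dub = evidence["dubious_flag"]
    val = evidence[method]
    return np.array(
        [
            [int((~dub & val).sum()), int((~dub & ~val).sum())],
            [int((dub & val).sum()), int((dub & ~val).sum())],
        ]
    )


def fisher_exact_log(table) -> float:
    """Two-sided Fisher exact test, returning log10(p).

    Computed entirely in log space: hypergeometric point probabilities
    via log-gamma, two-sided by summing (log-sum-exp) every table with
    the observed margins whose probability does not exceed the observed
    table's (with the usual 1+1e-7 relative tolerance).  Finite for any
    table; empty margins give p = 1 by convention.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with nonnegative counts")
    a, b = t[0]
    c, d = t[1]
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 0.0  # p = 1

    def logpmf(k: np.ndarray) -> np.ndarray:
        return (
            gammaln(r1 + 1) - gammaln(k + 1) - gammaln(r1 - k + 1)
            + gammaln(r2 + 1) - gammaln(c1 - k + 1) - gammaln(r2 - c1 + k + 1)
            + gammaln(c1 + 1) + gammaln(n - c1 + 1) - gammaln(n + 1)
        )

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    logs = logpmf(support)
    obs = logpmf(np.array([a]))[0]
    keep = logs <= obs + np.log1p(1e-7)
    logp = logsumexp(logs[keep])
    log10p = float(min(logp, 0.0) / np.log(10))
    # the full support sums to 1; tiny negative residue is rounding noise
    return 0.0 if log10p > -1e-9 else log10p
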