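"""Splicing Index computation and differential-expression selection plumbing.

For a gene with probe sets i and two conditions x in {1, 2}:

    NI_{i,x} = P_{i,x} / G_x          normalized intensity
    G_x      = mean_i P_{i,x}         gene-level signal (unweighted mean)
    SI_i     = log2(NI_{i,1} / NI_{i,2})

A gene with at least two probe sets is called alternatively spliced when any
of its probe sets has |SI| >= threshold (default 0.5). Replicate intensities
are averaged per condition before normalization; intensities are linear
scale and strictly positive (a flag accepts log2 input and exponentiates).

SI is invariant to condition-wide rescaling and antisymmetric under
condition swap; single-probe-set genes have NI = 1 and SI = 0 identically
and are ineligible for calling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

DEFAULT_SI_THRESHOLD = 0.5


@dataclass
class ExpressionMatrix:
    """Probe-set x sample intensity matrix with a sample -> condition map."""

    values: pd.DataFrame  # rows: probe_set_id, columns: sample_id
    conditions: dict[str, str]  # sample_id -> condition label

    def __post_init__(self) -> None:
        missing = set(self.values.columns) - set(self.conditions)
        if missing:
            raise ValueError(f"samples without condition labels: {sorted(missing)}")
        if (self.values.to_numpy() <= 0).any():
            raise ValueError("intensities must be strictly positive (linear scale)")

    @property
    def condition_labels(self) -> list[str]:
        seen: list[str] = []
        for s in self.values.columns:
            c = self.conditions[s]
            if c not in seen:
                seen.append(c)
        return seen

    def condition_means(self) -> pd.DataFrame:
        """Per-condition mean intensity (replicates averaged), one column per
        condition in first-appearance order."""
        cols = {}
        for cond in self.condition_labels:
            samples = [s for s in self.values.columns if self.conditions[s] == cond]
            cols[cond] = self.values[samples].mean(axis=1)
        return pd.DataFrame(cols)

    @classmethod
    def from_log2(cls, values: pd.DataFrame, conditions: dict[str, str]) -> "ExpressionMatrix":
        return cls(values=np.power(2.0, values), conditions=conditions)


def parse_expression_tsv(stream: Iterable[str] | IO[str], log2_input: bool = False) -> ExpressionMatrix:
    """TSV with header ``probe_set_id<TAB>sample:condition...``; '#' skipped."""
    lines = [l.rstrip("\n") for l in stream if l.strip() and not l.startswith("#")]
    header = lines[0].split("\t")
    samples, conditions = [], {}
    for col in header[1:]:
        if ":" not in col:
            raise ValueError(f"expression column {col!r} lacks a ':condition' suffix")
        sample, cond = col.rsplit(":", 1)
        samples.append(sample)
        conditions[sample] = cond
    rows, index = [], []
    for line in lines[1:]:
        parts = line.split("\t")
        index.append(parts[0])
        rows.append([float(x) for x in parts[1:]])
    values = pd.DataFrame(rows, index=index, columns=samples)
    if log2_input:
        return ExpressionMatrix.from_log2(values, conditions)
    return ExpressionMatrix(values=values, conditions=conditions)


def write_expression_tsv(matrix: ExpressionMatrix, stream: IO[str],
                         header: str | None = None) -> None:
    if header:
        for line in header.splitlines():
            stream.write(f"# {line}\n")
    cols = [f"{s}:{matrix.conditions[s]}" for s in matrix.values.columns]
    stream.write("probe_set_id\t" + "\t".join(cols) + "\n")
    for pid, row in matrix.values.iterrows():
        stream.write(pid + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# Gene signal and SI
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneSignal:
    """Per-condition gene-level signal: unweighted mean over probe sets."""

    values: tuple[float, ...]  # one per condition, in condition order

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.values):
            raise ValueError("gene signal must be positive")


def gene_signal(condition_means: pd.DataFrame) -> GeneSignal:
    """G_x = arithmetic mean over the gene's probe sets of condition means.

    ``condition_means`` is a probe-set x condition frame of positive values.
    """
    if condition_means.empty:
        raise ValueError("gene has no probe sets")
    if (condition_means.to_numpy() <= 0).any():
        raise ValueError("intensities must be strictly positive")
    return GeneSignal(tuple(float(v) for v in condition_means.mean(axis=0)))


@dataclass
class SpliceCall:
    gene_id: str
    probe_set_ids: list[str]
    ni: pd.DataFrame  # probe set x condition normalized intensities
    si: pd.Series  # per probe set
    called: bool
    threshold: float
    gene_expression: tuple[float, ...]  # G_x per condition


def splicing_index(condition_means: pd.DataFrame, gene_id: str = "",
                   threshold: float = DEFAULT_SI_THRESHOLD) -> SpliceCall:
    """Compute NI and SI for one gene from probe-set x condition means.

    Requires exactly two conditions and at least two probe sets (genes with
    a single probe set have SI identically zero and are ineligible).
    """
    if condition_means.shape[1] != 2:
        raise ValueError("splicing index requires exactly two conditions")
    if condition_means.shape[0] < 2:
        raise ValueError(
            f"gene {gene_id or '?'} has {condition_means.shape[0]} probe set(s); "
            "at least two are required"
        )
    if (condition_means.to_numpy() <= 0).any():
        raise ValueError("intensities must be strictly positive")
    g = gene_signal(condition_means)
    ni = condition_means / np.asarray(g.values)
    si = np.log2(ni.iloc[:, 0] / ni.iloc[:, 1])
    called = bool((si.abs() >= threshold).any())
    return SpliceCall(
        gene_id=gene_id,
        probe_set_ids=list(condition_means.index),
        ni=ni,
        si=si,
        called=called,
        threshold=threshold,
        gene_expression=g.values,
    )


def call_splice_variants(
    matrix: ExpressionMatrix,
    probe_set_gene: Mapping[str, str],
    threshold: float = DEFAULT_SI_THRESHOLD,
) -> pd.DataFrame:
    """Per-probe-set NI/SI table with gene-level calls for a whole matrix.

    Genes with fewer than two probe sets are skipped (reason recorded);
    their averaged gene signal is still reported. Columns: gene_id,
    probe_set_id, NI1, NI2, SI, called, skipped_reason.
    """
    missing = [p for p in matrix.values.index if p not in probe_set_gene]
    if missing:
        raise ValueError(f"probe sets without gene mapping: {missing[:5]}")
    means = matrix.condition_means()
    if means.shape[1] != 2:
        raise ValueError("splicing index requires exactly two conditions")
    rows = []
    genes: dict[str, list[str]] = {}
    for pid in matrix.values.index:
        genes.setdefault(probe_set_gene[pid], []).append(pid)
    for gene_id in sorted(genes):
        sets = genes[gene_id]
        sub = means.loc[sets]
        if len(sets) < 2:
            g = gene_signal(sub)
            rows.append(
                {
                    "gene_id": gene_id,
                    "probe_set_id": sets[0],
                    "NI1": 1.0,
                    "NI2": 1.0,
                    "SI": 0.0,
                    "called": False,
                    "gene_expr_1": g.values[0],
                    "gene_expr_2": g.values[1],
                    "skipped_reason": "single probe set",
                }
            )
            continue
        call = splicing_index(sub, gene_id=gene_id, threshold=threshold)
        for pid in sets:
            rows.append(
                {
                    "gene_id": gene_id,
                    "probe_set_id": pid,
                    "NI1": float(call.ni.loc[pid].iloc[0]),
                    "NI2": float(call.ni.loc[pid].iloc[1]),
                    "SI": float(call.si.loc[pid]),
                    "called": call.called,
                    "gene_expr_1": call.gene_expression[0],
                    "gene_expr_2": call.gene_expression[1],
                    "skipped_reason": "",
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# DE selection plumbing
# ---------------------------------------------------------------------------

def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, input order preserved."""
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return arr
    if np.any((arr < 0) | (arr > 1)) or np.any(np.isnan(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def select_de(
    log2fc: Sequence[float],
    adj_p: Sequence[float],
    gene_ids: Sequence[str] | None = None,
    p_thresh: float = 0.05,
    fc_thresh: float = 2.0,
) -> pd.DataFrame:
    """Select genes with adj_p strictly < ``p_thresh`` and fold change
    >= ``fc_thresh`` or <= 1/``fc_thresh`` (fold change = 2**log2fc).

    Returns the selected genes with up/down direction labels.
    """
    fc = np.power(2.0, np.asarray(log2fc, dtype=float))
    padj = np.asarray(adj_p, dtype=float)
    if fc.shape != padj.shape:
        raise ValueError("log2fc and adj_p must have matching lengths")
    ids = list(gene_ids) if gene_ids is not None else [str(i) for i in range(len(fc))]
    if len(ids) != len(fc):
        raise ValueError("gene_ids length mismatch")
    selected = (padj < p_thresh) & ((fc >= fc_thresh) | (fc <= 1.0 / fc_thresh))
    out = pd.DataFrame(
        {
            "gene_id": ids,
            "log2fc": np.asarray(log2fc, dtype=float),
            "fold_change": fc,
            "adj_p": padj,
        }
    )[selected]
    out["direction"] = np.where(out["fold_change"] >= 1.0, "up", "down")
    return out.reset_index(drop=True)
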