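"""Consensus labels and inter-/intra-reviewer agreement statistics.

Ground truth for this task is the consensus of a five-expert morphology
panel.  This module derives per-cell consensus labels (plurality vote with
a documented tie-break), scores each reviewer against a reference with the
standard metric panel, and computes Pearson correlation matrices over a
maturity-ordered numeric label encoding (monocyte=0, promonocyte=1,
blast=2 — the monocytic maturation scale), including the repeat pass of
the designated intra-rater reviewer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from monoclass.classifier import merge_labels
from monoclass.evaluation import MetricPanel, SummaryStats, compute_metrics, summarize
from monoclass.synthetic_cells import CLASSES, CellRecord

# maturity-ordered encodings; Pearson on labels presumes this ordinal scale
THREE_CLASS_ENCODING: dict[str, int] = {"monocyte": 0, "promonocyte": 1, "blast": 2}
MERGED_ENCODING: dict[str, int] = {"monocyte": 0, "precursor": 1}

# maturity order for tie-breaking: most mature first
_MATURITY_ORDER = ("monocyte", "promonocyte", "blast")


@dataclass
class ReviewerPanelTable:
    """Cells x reviewers label matrix, with an optional repeat-pass column."""

    cells: list[str]
    labels: pd.DataFrame                  # index: cells, columns: reviewer_1..n
    repeat_labels: pd.Series | None = None
    repeat_reviewer_index: int = 4        # 0-based column of the repeating reviewer

    def __post_init__(self) -> None:
        if self.labels.isna().any().any():
            raise ValueError("reviewer panel contains missing labels")
        if self.repeat_labels is not None and not self.labels.index.equals(self.repeat_labels.index):
            raise ValueError("repeat column not aligned to the panel cells")

    @property
    def n_reviewers(self) -> int:
        return self.labels.shape[1]

    @classmethod
    def from_records(cls, records: list[CellRecord]) -> "ReviewerPanelTable":
        """Build a panel from simulated records (reviewer_labels filled)."""
        if not records:
            raise ValueError("empty record list")
        if any(r.reviewer_labels is None for r in records):
            raise ValueError("records lack reviewer labels; run simulate_reviewers first")
        cells = [r.cell_id for r in records]
        nrev = len(records[0].reviewer_labels)
        df = pd.DataFrame(
            [r.reviewer_labels for r in records],
            index=cells, columns=[f"reviewer_{i + 1}" for i in range(nrev)],
        )
        rep = None
        if all(r.repeat_label is not None for r in records):
            rep = pd.Series([r.repeat_label for r in records], index=cells)
        return cls(cells=cells, labels=df, repeat_labels=rep)


def consensus(panel: ReviewerPanelTable) -> pd.DataFrame:
    """Per-cell plurality consensus.

    Ties are broken toward the least mature class among the tied labels
    (blast over promonocyte over monocyte) — the conservative convention
    for blast-equivalent counting — and tied cells are flagged.  Returns a
    DataFrame with columns ``consensus`` and ``tied``.
    """
    if len(panel.cells) == 0:
        raise ValueError("empty panel")
    if panel.n_reviewers < 3:
        raise ValueError("consensus needs at least 3 reviewers")
    out = []
    for cell_id, row in panel.labels.iterrows():
        counts = row.value_counts()
        top = counts.max()
        tied_labels = [c for c in counts.index if counts[c] == top]
        tied = len(tied_labels) > 1
        winner = max(tied_labels, key=_MATURITY_ORDER.index)
        out.append((cell_id, winner, tied))
    return pd.DataFrame(out, columns=["cell_id", "consensus", "tied"]).set_index("cell_id")


def reviewer_vs_reference(panel: ReviewerPanelTable, reference_labels,
                          scheme: str = "3-class"):
    """Score each reviewer against the reference labels.

    Returns (per-reviewer dict of MetricPanel, dict of SummaryStats across
    reviewers for each metric).  The 2-class scheme merges promonocyte and
    blast into 'precursor' on both sides before scoring.
    """
    reference = pd.Series(list(reference_labels), index=panel.labels.index)
    if len(reference) != len(panel.cells):
        raise ValueError("reference labels misaligned with panel cells")
    if scheme == "2-class":
        reference = pd.Series(merge_labels(reference), index=reference.index)
        classes = ("monocyte", "precursor")
    elif scheme == "3-class":
        classes = CLASSES
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    panels: dict[str, MetricPanel] = {}
    for col in panel.labels.columns:
        rev = panel.labels[col]
        if scheme == "2-class":
            rev = pd.Series(merge_labels(rev), index=rev.index)
        panels[col] = compute_metrics(reference, rev, classes=classes)
    summaries = {
        m: summarize([getattr(p, m) for p in panels.values()])
        for m in ("accuracy", "precision", "recall", "f1")
    }
    return panels, summaries


def _encode_column(values, encoding: dict[str, int]) -> np.ndarray:
    try:
        return np.array([encoding[v] for v in values], dtype=float)
    except KeyError as e:
        raise ValueError(f"label {e.args[0]!r} not encodable with {encoding}") from e


def pearson_matrix(panel: ReviewerPanelTable, reference_labels=None,
                   encoding: dict[str, int] = THREE_CLASS_ENCODING) -> pd.DataFrame:
    """Pearson correlation matrix over reviewers (+ repeat pass, + reference).

    Labels are encoded on the maturity-ordered numeric scale first.  A
    constant column has undefined correlation: its entries are reported as
    NaN with a warning.  The result is symmetric with unit diagonal.
    """
    if len(panel.cells) < 2:
        raise ValueError("pearson_matrix needs at least 2 cells")
    cols: dict[str, np.ndarray] = {
        col: _encode_column(panel.labels[col], encoding) for col in panel.labels.columns
    }
    if panel.repeat_labels is not None:
        rep_name = f"{panel.labels.columns[panel.repeat_reviewer_index]}R"
        cols[rep_name] = _encode_column(panel.repeat_labels, encoding)
    if reference_labels is not None:
        cols["reference"] = _encode_column(list(reference_labels), encoding)

    names = list(cols)
    mat = np.vstack([cols[c] for c in names])
    constant = mat.std(axis=1) == 0
    if constant.any():
        bad = [names[i] for i in np.flatnonzero(constant)]
        warnings.warn(f"constant label column(s) {bad}: correlation undefined, reported as NaN")
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(mat)
    corr[constant, :] = np.nan
    corr[:, constant] = np.nan
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=names, columns=names)


def intra_reviewer(panel: ReviewerPanelTable,
                   encoding: dict[str, int] = THREE_CLASS_ENCODING) -> float:
    """Pearson r between the designated reviewer's first and repeat pass."""
    if panel.repeat_labels is None:
        raise ValueError("panel has no repeat-pass column")
    first = _encode_column(panel.labels.iloc[:, panel.repeat_reviewer_index], encoding)
    second = _encode_column(panel.repeat_labels, encoding)
    if first.std() == 0 or second.std() == 0:
        if np.array_equal(first, second):
            return 1.0
        raise ValueError("constant label column: correlation undefined")
    return float(np.corrcoef(first, second)[0, 1])
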