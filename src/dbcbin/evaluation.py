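"""Cross-validation of bin assignments against known contig origins.

Sensitivity is tp / (tp + fn) over contigs for which a trained bin exists;
specificity is tn / (tn + fp) over contigs with no trained bin, where a
negative call means the contig was left unbinned by the distance/length
cut-offs. A contig counts as a true positive when its true bin appears
among its best `top_n` ranked bins (the "best two bins" rule at top_n=2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .classify import (
    BINNED,
    UNBINNED_DISTANCE,
    UNBINNED_SHORT,
    UNBINNED_UNSIGNABLE,
    Assignment,
    BinningParams,
    _rank,
)
from .sequence_io import SequenceRecord
from .signature import UnsignableSequenceError, compute_signature
from .training import SignatureLibrary

__all__ = [
    "NO_BIN",
    "UNBINNED",
    "TruthTable",
    "EvaluationResult",
    "score_assignments",
    "sweep_cutoffs",
    "write_report",
]

NO_BIN = "NO_BIN"  # truth token: no trained bin exists for this contig
UNBINNED = "unbinned"  # confusion-matrix column for rejected contigs


@dataclass
class TruthTable:
    """True bin per contig id, plus the ids with no trained bin available."""

    labels: dict[str, str] = field(default_factory=dict)
    no_bin: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        overlap = set(self.labels) & self.no_bin
        if overlap:
            raise ValueError(f"ids both labeled and in the no-bin set: {sorted(overlap)[:5]}")

    def __len__(self) -> int:
        return len(self.labels) + len(self.no_bin)

    def __contains__(self, sequence_id: str) -> bool:
        return sequence_id in self.labels or sequence_id in self.no_bin

    @classmethod
    def read_tsv(cls, path: Union[str, Path]) -> "TruthTable":
        """Two-column TSV: sequence_id, true bin (NO_BIN marks the no-bin set)."""
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"truth table not found: {path}")
        labels: dict[str, str] = {}
        no_bin: set[str] = set()
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line.strip() or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) != 2:
                    raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
                sid, label = fields
                if sid in labels or sid in no_bin:
                    raise ValueError(f"{path}:{lineno}: duplicate sequence id {sid!r}")
                if label == NO_BIN:
                    no_bin.add(sid)
                else:
                    labels[sid] = label
        return cls(labels=labels, no_bin=no_bin)

    def write_tsv(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            fh.write("# dbcbin truth table\n")
            for sid, label in self.labels.items():
                fh.write(f"{sid}\t{label}\n")
            for sid in sorted(self.no_bin):
                fh.write(f"{sid}\t{NO_BIN}\n")


@dataclass
class EvaluationResult:
    """Confusion counts and the derived sensitivity/specificity.

    Undefined ratios (zero denominator) are None, never coerced to 0 or 1.
    `confusion` is true-bin rows (including NO_BIN) by assigned-bin columns
    (including an 'unbinned' column); rows sum to per-true-bin input counts.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float | None
    specificity: float | None
    confusion: pd.DataFrame
    top_n: int

    @property
    def n_evaluated(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def score_assignments(
    assignments: Sequence[Assignment],
    truth: TruthTable,
    top_n: int = 1,
    label_map: Mapping[str, str] | None = None,
) -> EvaluationResult:
    """Score assignments against the truth table.

    `label_map` optionally maps bin names (both assigned and true) to a
    coarser rank — e.g. genus bins to their class — before comparison, so
    the same assignments can be scored at several taxonomic levels.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    remap: Callable[[str], str] = (
        (lambda name: label_map.get(name, name)) if label_map is not None else (lambda name: name)
    )
    tp = fp = tn = fn = 0
    rows: list[tuple[str, str]] = []
    for a in assignments:
        if a.status == BINNED and len(a.ranked_bins) < top_n:
            raise ValueError(
                f"contig {a.sequence_id!r}: top_n={top_n} exceeds the "
                f"{len(a.ranked_bins)} ranked bins available"
            )
        if a.sequence_id in truth.no_bin:
            true_label = NO_BIN
            if a.status == BINNED:
                fp += 1
                assigned = remap(a.ranked_bins[0][0])
            else:
                tn += 1
                assigned = UNBINNED
        elif a.sequence_id in truth.labels:
            true_label = remap(truth.labels[a.sequence_id])
            if a.status == BINNED:
                top = [remap(name) for name, _ in a.ranked_bins[:top_n]]
                assigned = top[0]
                if true_label in top:
                    tp += 1
                else:
                    fn += 1
            else:
                fn += 1
                assigned = UNBINNED
        else:
            raise KeyError(f"contig {a.sequence_id!r} missing from the truth table")
        rows.append((true_label, assigned))
    confusion = pd.crosstab(
        pd.Series([r[0] for r in rows], name="true_bin"),
        pd.Series([r[1] for r in rows], name="assigned_bin"),
    )
    sensitivity = tp / (tp + fn) if (tp + fn) > 0 else None
    specificity = tn / (tn + fp) if (tn + fp) > 0 else None
    return EvaluationResult(
        tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=sensitivity, specificity=specificity,
        confusion=confusion, top_n=top_n,
    )


def sweep_cutoffs(
    records: Sequence[SequenceRecord],
    lib: SignatureLibrary,
    truth: TruthTable,
    length_grid: Sequence[int],
    distance_grid: Sequence[float | None],
    params: BinningParams | None = None,
    top_n: int = 1,
) -> pd.DataFrame:
    """Evaluate every (min_length, max_distance) grid point.

    Signatures (and centroid distances) are computed once per record and
    reused across the grid. A distance of None (or inf) disables the
    distance cut-off at that grid point. Each grid point's length cut-off
    defines the candidate pool: contigs below min_length are excluded from
    that evaluation entirely (the run "bins all contigs longer than
    min_length"), while the distance cut-off determines negatives within
    the pool.
    """
    if not length_grid or not len(distance_grid):
        raise ValueError("length_grid and distance_grid must be non-empty")
    if params is None:
        params = BinningParams(k=lib.k)
    if params.k != lib.k:
        raise ValueError(f"params k={params.k} does not match library k={lib.k}")
    names = lib.names
    centroids = lib.centroid_matrix()

    cached: list[tuple[str, int, list[tuple[str, float]] | None]] = []
    for rec in records:
        try:
            sig = compute_signature(rec, k=params.k, lam=params.lam, tol=params.tol)
        except UnsignableSequenceError:
            cached.append((rec.id, rec.length, None))
            continue
        cached.append((rec.id, rec.length, _rank(sig.vector, names, centroids, params.metric)))

    out_rows = []
    for min_length in length_grid:
        for max_distance in distance_grid:
            cutoff = None if max_distance is None or np.isinf(max_distance) else max_distance
            assignments = []
            for sid, length, ranked in cached:
                if length < min_length:
                    continue
                if ranked is None:
                    assignments.append(Assignment(sid, UNBINNED_UNSIGNABLE))
                elif cutoff is not None and ranked[0][1] > cutoff:
                    assignments.append(Assignment(sid, UNBINNED_DISTANCE, ranked[:top_n]))
                else:
                    assignments.append(Assignment(sid, BINNED, ranked[:top_n]))
            res = score_assignments(assignments, truth, top_n=top_n)
            out_rows.append(
                {
                    "min_length": min_length,
                    "max_distance": np.inf if cutoff is None else cutoff,
                    "n_binned": sum(a.status == BINNED for a in assignments),
                    "tp": res.tp,
                    "fp": res.fp,
                    "tn": res.tn,
                    "fn": res.fn,
                    "sensitivity": np.nan if res.sensitivity is None else res.sensitivity,
                    "specificity": np.nan if res.specificity is None else res.specificity,
                }
            )
    return pd.DataFrame(out_rows)


def _fmt_ratio(x: float | None) -> str:
    return "n/a" if x is None else format(x, ".6f")


def write_report(result: EvaluationResult, path: Union[str, Path]) -> None:
    """Write a summary block plus the confusion matrix as TSV."""
    with open(path, "w") as fh:
        fh.write("# dbcbin evaluation report\n")
        fh.write(f"# top_n={result.top_n}\n")
        fh.write(f"# tp={result.tp}\tfp={result.fp}\ttn={result.tn}\tfn={result.fn}\n")
        fh.write(f"# sensitivity={_fmt_ratio(result.sensitivity)}\n")
        fh.write(f"# specificity={_fmt_ratio(result.specificity)}\n")
        result.confusion.to_csv(fh, sep="\t")
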