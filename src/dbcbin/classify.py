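"""Nearest-centroid assignment of query contigs to trained bins.

Each signable contig at least `min_length` bases long is assigned to the
bin with the nearest centroid; contigs failing the length, signability or
(optional) distance cut-off are routed to an explicit unbinned pool so
that counts are always conserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np

from .sequence_io import SequenceRecord
from .signature import UnsignableSequenceError, compute_signature, vector_distance
from .training import SignatureLibrary

__all__ = [
    "BINNED",
    "UNBINNED_SHORT",
    "UNBINNED_DISTANCE",
    "UNBINNED_UNSIGNABLE",
    "STATUSES",
    "BinningParams",
    "Assignment",
    "classify_one",
    "bin_metagenome",
    "write_assignments",
    "read_assignments",
]

BINNED = "binned"
UNBINNED_SHORT = "unbinned_short"
UNBINNED_DISTANCE = "unbinned_distance"
UNBINNED_UNSIGNABLE = "unbinned_unsignable"
STATUSES = (BINNED, UNBINNED_SHORT, UNBINNED_DISTANCE, UNBINNED_UNSIGNABLE)

_NA = "NA"


@dataclass(frozen=True)
class BinningParams:
    """Cut-offs and signature parameters for one classification run.

    max_distance None disables the distance cut-off (every signable contig
    of sufficient length is assigned).
    """

    k: int = 3
    lam: float = 0.01
    tol: float = 1e-12
    metric: str = "euclidean"
    min_length: int = 1000
    max_distance: float | None = None
    report_top_n: int = 2

    def __post_init__(self) -> None:
        if self.min_length < self.k + 1:
            raise ValueError(
                f"min_length {self.min_length} must be >= k+1 = {self.k + 1}"
            )
        if self.report_top_n < 1:
            raise ValueError("report_top_n must be >= 1")
        if self.max_distance is not None and self.max_distance < 0:
            raise ValueError("max_distance must be non-negative")


@dataclass
class Assignment:
    """Result for one contig: a bin call or an explicit unbinned status."""

    sequence_id: str
    status: str
    ranked_bins: list[tuple[str, float]] = field(default_factory=list)

    @property
    def best_bin(self) -> str | None:
        return self.ranked_bins[0][0] if self.status == BINNED else None

    @property
    def best_distance(self) -> float | None:
        return self.ranked_bins[0][1] if self.ranked_bins else None


def _check_params(lib: SignatureLibrary, params: BinningParams) -> None:
    if not lib.bins:
        raise ValueError("signature library is empty")
    if params.k != lib.k:
        raise ValueError(
            f"word-length mismatch: parameters use k={params.k} but the "
            f"library was built at k={lib.k}"
        )


def _rank(
    vector: np.ndarray,
    names: Sequence[str],
    centroids: np.ndarray,
    metric: str,
) -> list[tuple[str, float]]:
    if metric == "euclidean":
        dists = np.linalg.norm(centroids - vector, axis=1)
    else:
        dists = np.array(
            [vector_distance(vector, c, metric=metric) for c in centroids]
        )
    # ties at exactly equal distance break lexicographically on bin name
    return sorted(zip(names, (float(d) for d in dists)), key=lambda t: (t[1], t[0]))


def classify_one(
    record: SequenceRecord,
    lib: SignatureLibrary,
    params: BinningParams = BinningParams(),
    _centroids: tuple[Sequence[str], np.ndarray] | None = None,
) -> Assignment:
    """Assign one contig to its nearest bin centroid under the cut-offs."""
    _check_params(lib, params)
    if record.length < params.min_length:
        return Assignment(record.id, UNBINNED_SHORT)
    try:
        sig = compute_signature(record, k=params.k, lam=params.lam, tol=params.tol)
    except UnsignableSequenceError:
        return Assignment(record.id, UNBINNED_UNSIGNABLE)
    names, centroids = _centroids if _centroids is not None else (
        lib.names,
        lib.centroid_matrix(),
    )
    ranked = _rank(sig.vector, names, centroids, params.metric)[: params.report_top_n]
    if params.max_distance is not None and ranked[0][1] > params.max_distance:
        return Assignment(record.id, UNBINNED_DISTANCE, ranked)
    return Assignment(record.id, BINNED, ranked)


def bin_metagenome(
    records: Iterable[SequenceRecord],
    lib: SignatureLibrary,
    params: BinningParams = BinningParams(),
) -> tuple[list[Assignment], dict]:
    """Classify every record, preserving input order.

    Returns the assignments and a summary dict with per-status counts and
    per-bin binned counts. Deterministic given inputs and parameters.
    """
    _check_params(lib, params)
    cached = (lib.names, lib.centroid_matrix())
    assignments: list[Assignment] = []
    status_counts = {s: 0 for s in STATUSES}
    per_bin: dict[str, int] = {name: 0 for name in lib.names}
    for record in records:
        a = classify_one(record, lib, params, _centroids=cached)
        assignments.append(a)
        status_counts[a.status] += 1
        if a.status == BINNED:
            per_bin[a.best_bin] += 1
    summary = {"n_records": len(assignments), **status_counts, "per_bin": per_bin}
    return assignments, summary


def write_assignments(
    assignments: Sequence[Assignment],
    path: Union[str, Path],
    params: BinningParams = BinningParams(),
    extra_header: dict[str, str] | None = None,
) -> None:
    """Write assignments as TSV with '#' provenance headers."""
    top_n = params.report_top_n
    with open(path, "w") as fh:
        fh.write("# dbcbin assignments\n")
        header = {
            "k": params.k,
            "lambda": params.lam,
            "tol": params.tol,
            "metric": params.metric,
            "min_length": params.min_length,
            "max_distance": params.max_distance if params.max_distance is not None else "disabled",
            "report_top_n": top_n,
        }
        header.update(extra_header or {})
        for key, value in header.items():
            fh.write(f"# {key}={value}\n")
        cols = ["sequence_id", "status"]
        for i in range(1, top_n + 1):
            cols += [f"bin_{i}", f"distance_{i}"]
        fh.write("#" + "\t".join(cols) + "\n")
        for a in assignments:
            fields = [a.sequence_id, a.status]
            for i in range(top_n):
                if i < len(a.ranked_bins):
                    name, dist = a.ranked_bins[i]
                    fields += [name, format(dist, ".17g")]
                else:
                    fields += [_NA, _NA]
            fh.write("\t".join(fields) + "\n")


def read_assignments(path: Union[str, Path]) -> list[Assignment]:
    """Read a file written by :func:`write_assignments`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"assignments file not found: {path}")
    out: list[Assignment] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2 or len(fields) % 2 != 0:
                raise ValueError(f"{path}:{lineno}: malformed assignment row")
            sid, status = fields[0], fields[1]
            if status not in STATUSES:
                raise ValueError(f"{path}:{lineno}: unknown status {status!r}")
            ranked: list[tuple[str, float]] = []
            for i in range(2, len(fields), 2):
                if fields[i] == _NA:
                    break
                ranked.append((fields[i], float(fields[i + 1])))
            out.append(Assignment(sid, status, ranked))
    return out
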