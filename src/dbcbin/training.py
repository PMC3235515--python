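"""Training bins and signature libraries.

A bin is a named training set: the centroid of its members' signatures is
what queries are compared against. A signature library bundles bins computed
at one word length together with the parameters used, and serializes to a
diff-able tab-separated text format with full decimal precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np

from .sequence_io import SequenceRecord, read_fasta
from .signature import (
    DBCSignature,
    UnsignableSequenceError,
    compute_signature,
    index_word,
    vector_distance,
)

__all__ = [
    "Bin",
    "SignatureLibrary",
    "LibraryFormatError",
    "build_bin",
    "save_library",
    "load_library",
    "precompute_signatures",
    "calibrate_distance_cutoff",
]

logger = logging.getLogger(__name__)

FORMAT_VERSION = "1"


class LibraryFormatError(ValueError):
    """Malformed signature-library file; message carries the line number."""


@dataclass
class Bin:
    """A named training set with its centroid signature."""

    name: str
    k: int
    centroid: np.ndarray
    taxon_label: str = ""
    n_members: int = 0
    n_bases_trained: int = 0
    member_signatures: list[DBCSignature] | None = field(default=None, repr=False)


@dataclass
class SignatureLibrary:
    """Named bins at one word length k, plus the creation parameters."""

    k: int
    bins: dict[str, Bin]
    metadata: dict[str, str] = field(default_factory=dict)

    @property
    def names(self) -> list[str]:
        return list(self.bins)

    def centroid_matrix(self) -> np.ndarray:
        """Bin centroids stacked row-wise, in library order."""
        return np.vstack([b.centroid for b in self.bins.values()])

    def subset(self, names: Iterable[str]) -> "SignatureLibrary":
        """New library keeping only the named bins (order preserved)."""
        names = list(names)
        missing = [n for n in names if n not in self.bins]
        if missing:
            raise KeyError(f"bins not in library: {missing}")
        return SignatureLibrary(
            k=self.k,
            bins={n: self.bins[n] for n in self.names if n in set(names)},
            metadata=dict(self.metadata),
        )

    def bins_with_label_prefix(self, prefix: str) -> list[str]:
        """Names of bins whose taxon label starts with `prefix`.

        Stands in for picking a node of a taxonomy tree: selecting
        "Bacteria;Proteobacteria" selects every bin filed under it.
        """
        return [n for n, b in self.bins.items() if b.taxon_label.startswith(prefix)]


def _default_metadata(k: int, lam: float, tol: float, metric: str) -> dict[str, str]:
    return {
        "version": FORMAT_VERSION,
        "k": str(k),
        "lambda": repr(lam),
        "tol": repr(tol),
        "metric": metric,
    }


def build_bin(
    name: str,
    records: Sequence[SequenceRecord],
    k: int = 3,
    lam: float = 0.01,
    tol: float = 1e-12,
    min_train_length: int = 1000,
    taxon_label: str = "",
    length_weighted: bool = False,
) -> Bin:
    """Compute one signature per qualifying record and average into a bin.

    Records shorter than max(k+1, min_train_length) or without a signable
    segment are skipped (counted and logged). The centroid is the plain
    arithmetic mean of member signatures unless `length_weighted` is set,
    in which case members are weighted by their sequence length.
    """
    threshold = max(k + 1, min_train_length)
    members: list[DBCSignature] = []
    lengths: list[int] = []
    skipped = 0
    for rec in records:
        if rec.length < threshold:
            skipped += 1
            continue
        try:
            sig = compute_signature(rec, k=k, lam=lam, tol=tol)
        except UnsignableSequenceError:
            skipped += 1
            continue
        members.append(sig)
        lengths.append(rec.length)
    if not members:
        raise ValueError(
            f"bin {name!r}: no training record of length >= {threshold} "
            f"with a signable ACGT segment"
        )
    if skipped:
        logger.info("bin %s: skipped %d record(s) below the training cutoff", name, skipped)
    weights = np.array(lengths, dtype=float) if length_weighted else None
    centroid = np.average(np.vstack([m.vector for m in members]), axis=0, weights=weights)
    return Bin(
        name=name,
        k=k,
        centroid=centroid,
        taxon_label=taxon_label,
        n_members=len(members),
        n_bases_trained=int(sum(lengths)),
        member_signatures=members,
    )


def save_library(lib: SignatureLibrary, path: Union[str, Path]) -> None:
    """Write a library as tab-separated text (17-significant-digit floats)."""
    if not lib.bins:
        raise ValueError("refusing to save an empty library (needs >= 1 bin)")
    path = Path(path)
    words = [index_word(i, lib.k) for i in range(4**lib.k)]
    meta = dict(lib.metadata) or _default_metadata(lib.k, 0.01, 1e-12, "euclidean")
    meta["version"] = FORMAT_VERSION
    meta["k"] = str(lib.k)
    with open(path, "w") as fh:
        fh.write("# dbcbin signature library\n")
        for key, value in meta.items():
            fh.write(f"# {key}={value}\n")
        fh.write("#name\ttaxon_label\tn_members\tn_bases_trained\t" + "\t".join(words) + "\n")
        for b in lib.bins.values():
            if len(b.centroid) != 4**lib.k:
                raise ValueError(
                    f"bin {b.name!r}: centroid length {len(b.centroid)} "
                    f"inconsistent with k={lib.k}"
                )
            values = "\t".join(format(x, ".17g") for x in b.centroid)
            fh.write(
                f"{b.name}\t{b.taxon_label}\t{b.n_members}\t{b.n_bases_trained}\t{values}\n"
            )


def load_library(path: Union[str, Path]) -> SignatureLibrary:
    """Read a library written by :func:`save_library` (lossless round-trip)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"signature library not found: {path}")
    meta: dict[str, str] = {}
    bins: dict[str, Bin] = {}
    k: int | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body and "\t" not in body:
                    key, _, value = body.partition("=")
                    meta[key.strip()] = value.strip()
                continue
            if k is None:
                if "k" not in meta:
                    raise LibraryFormatError(f"{path}:{lineno}: header lacks 'k='")
                if meta.get("version") != FORMAT_VERSION:
                    raise LibraryFormatError(
                        f"{path}: format version {meta.get('version')!r} "
                        f"not supported (expected {FORMAT_VERSION!r})"
                    )
                k = int(meta["k"])
            fields = line.split("\t")
            expected = 4 + 4**k
            if len(fields) != expected:
                raise LibraryFormatError(
                    f"{path}:{lineno}: row for bin {fields[0]!r} has "
                    f"{len(fields)} columns, expected {expected} for k={k}"
                )
            name, taxon_label, n_members, n_bases = fields[:4]
            if name in bins:
                raise LibraryFormatError(f"{path}:{lineno}: duplicate bin name {name!r}")
            try:
                centroid = np.array([float(x) for x in fields[4:]])
            except ValueError as exc:
                raise LibraryFormatError(f"{path}:{lineno}: {exc}") from None
            bins[name] = Bin(
                name=name,
                k=k,
                centroid=centroid,
                taxon_label=taxon_label,
                n_members=int(n_members),
                n_bases_trained=int(n_bases),
            )
    if k is None:
        if "k" not in meta:
            raise LibraryFormatError(f"{path}: header lacks 'k='")
        if meta.get("version") != FORMAT_VERSION:
            raise LibraryFormatError(
                f"{path}: format version {meta.get('version')!r} not supported"
            )
        raise LibraryFormatError(f"{path}: library contains no bins")
    return SignatureLibrary(k=k, bins=bins, metadata=meta)


def precompute_signatures(
    fasta_paths: Sequence[Union[str, Path]],
    labels: Sequence[str],
    k: int = 3,
    lam: float = 0.01,
    tol: float = 1e-12,
    min_train_length: int = 1000,
    taxon_labels: Sequence[str] | None = None,
    metric: str = "euclidean",
) -> SignatureLibrary:
    """Train one bin per label from FASTA files; paths sharing a label pool.

    Pooling lets several isolate genomes train a single higher-rank bin.
    """
    if len(fasta_paths) != len(labels):
        raise ValueError("fasta_paths and labels must have equal length")
    if taxon_labels is not None and len(taxon_labels) != len(labels):
        raise ValueError("taxon_labels must align with labels")
    grouped: dict[str, list[SequenceRecord]] = {}
    taxa: dict[str, str] = {}
    for i, (path, label) in enumerate(zip(fasta_paths, labels)):
        grouped.setdefault(label, []).extend(read_fasta(path))
        if taxon_labels is not None:
            taxa[label] = taxon_labels[i]
    bins = {
        label: build_bin(
            label,
            records,
            k=k,
            lam=lam,
            tol=tol,
            min_train_length=min_train_length,
            taxon_label=taxa.get(label, ""),
        )
        for label, records in grouped.items()
    }
    return SignatureLibrary(k=k, bins=bins, metadata=_default_metadata(k, lam, tol, metric))


def calibrate_distance_cutoff(
    lib: SignatureLibrary, quantile: float = 0.99, metric: str = "euclidean"
) -> float:
    """Distance cutoff from training data: a quantile of the distances of
    member signatures to their own bin centroid.

    Queries farther than this from every centroid are plausibly from taxa
    the library does not cover and should be rejected rather than forced
    into the nearest bin. Requires a library that still holds member
    signatures (i.e. built in this session, not loaded from disk).
    """
    if not 0.0 < quantile <= 1.0:
        raise ValueError(f"quantile must lie in (0, 1], got {quantile}")
    distances: list[float] = []
    for b in lib.bins.values():
        if not b.member_signatures:
            raise ValueError(
                f"bin {b.name!r} has no member signatures; "
                f"calibration needs a freshly trained library"
            )
        for sig in b.member_signatures:
            distances.append(vector_distance(sig.vector, b.centroid, metric=metric))
    return float(np.quantile(distances, quantile))
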