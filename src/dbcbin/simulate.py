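"""Seeded synthetic genomes and metagenomes with known bin membership.

Genomes are sampled from order-m Markov models over A/C/G/T. A family of
models shares a base transition table; each model mixes in its own
near-deterministic base preferences with weight `separation`, so a single
knob controls compositional divergence between models: separation 0 makes
the models identical, 1 maximally distinct, and the total-variation
distance between corresponding rows grows linearly in between.

All generation fans a single seed out through ``numpy.random.SeedSequence``
spawning, so per-model and per-contig streams are independent and adding a
model does not perturb the sequences of the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import numpy as np

from .evaluation import TruthTable
from .sequence_io import SequenceRecord, write_fasta

__all__ = [
    "GenomeModel",
    "SyntheticMetagenome",
    "make_models",
    "generate_genome",
    "fragment_genome",
    "generate_metagenome",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class GenomeModel:
    """Order-m Markov model: 4**m context rows over the next-base alphabet."""

    model_id: str
    order: int
    transition: np.ndarray  # shape (4**m, 4), rows sum to 1

    def __post_init__(self) -> None:
        expected = (4**self.order, 4)
        if self.transition.shape != expected:
            raise ValueError(
                f"transition matrix shape {self.transition.shape} != {expected}"
            )
        if np.any(self.transition < 0) or not np.allclose(
            self.transition.sum(axis=1), 1.0, atol=1e-12
        ):
            raise ValueError("transition rows must be non-negative and sum to 1")


@dataclass
class SyntheticMetagenome:
    """Labeled contig set: records plus the truth table used to score them."""

    records: list[SequenceRecord]
    truth: TruthTable
    params: dict = field(default_factory=dict)

    def write(self, fasta_path: Union[str, Path], truth_path: Union[str, Path]) -> None:
        write_fasta(self.records, fasta_path)
        self.truth.write_tsv(truth_path)


def make_models(
    n_models: int,
    separation: float,
    seed: int,
    order: int = 3,
    base_concentration: float = 10.0,
    pref_concentration: float = 0.4,
) -> list[GenomeModel]:
    """Deterministic family of Markov models at a controlled divergence.

    Rows are (1 - separation) * shared_base + separation * model_preference,
    with base rows ~ Dirichlet(base_concentration) (smooth, shared) and
    preference rows ~ Dirichlet(pref_concentration) (spiky, per model).
    """
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    if not 0.0 <= separation <= 1.0:
        raise ValueError(f"separation must lie in [0, 1], got {separation}")
    n_ctx = 4**order
    root = np.random.SeedSequence(seed)
    children = root.spawn(n_models + 1)
    base = np.random.default_rng(children[0]).dirichlet(
        base_concentration * np.ones(4), size=n_ctx
    )
    models = []
    for i in range(n_models):
        pref = np.random.default_rng(children[i + 1]).dirichlet(
            pref_concentration * np.ones(4), size=n_ctx
        )
        rows = (1.0 - separation) * base + separation * pref
        models.append(GenomeModel(model_id=f"model{i:02d}", order=order, transition=rows))
    return models


def _sample_codes(model: GenomeModel, length: int, rng: np.random.Generator) -> np.ndarray:
    m = model.order
    mask = 4**m - 1  # 4**m is a power of two, so bit-masking rolls the context
    cum = np.cumsum(model.transition, axis=1).tolist()
    codes = np.empty(length, dtype=np.int64)
    init = rng.integers(0, 4, size=m)
    codes[:m] = init
    ctx = 0
    for b in init:
        ctx = (ctx << 2) | int(b)
    u = rng.random(length - m)
    for t in range(length - m):
        row = cum[ctx]
        x = u[t]
        b = 0 if x < row[0] else 1 if x < row[1] else 2 if x < row[2] else 3
        codes[m + t] = b
        ctx = ((ctx << 2) | b) & mask
    return codes


def generate_genome(
    model: GenomeModel,
    length: int,
    seed: Union[int, np.random.SeedSequence],
    record_id: str | None = None,
) -> SequenceRecord:
    """Sample one sequence base-by-base from the model; deterministic per seed."""
    if length < model.order + 1:
        raise ValueError(f"length must be >= order+1 = {model.order + 1}")
    rng = np.random.default_rng(seed)
    codes = _sample_codes(model, length, rng)
    return SequenceRecord(
        id=record_id or f"{model.model_id}_genome",
        sequence=_BASES[codes].tobytes().decode("ascii"),
        description=f"synthetic order-{model.order} Markov genome",
    )


def _log_uniform_lengths(
    rng: np.random.Generator, n: int, min_length: int, max_length: int
) -> np.ndarray:
    """Log-uniform contig lengths, echoing assembled-contig length skew."""
    if not 1 <= min_length <= max_length:
        raise ValueError(f"invalid length bounds [{min_length}, {max_length}]")
    draws = np.exp(rng.uniform(np.log(min_length), np.log(max_length), size=n))
    return np.clip(np.rint(draws).astype(int), min_length, max_length)


def fragment_genome(
    genome: SequenceRecord,
    n_fragments: int,
    length_range: tuple[int, int],
    seed: Union[int, np.random.SeedSequence],
    id_prefix: str | None = None,
) -> list[SequenceRecord]:
    """Random (possibly overlapping) fragments of one genome, log-uniform sizes."""
    rng = np.random.default_rng(seed)
    lo, hi = length_range
    hi = min(hi, genome.length)
    lengths = _log_uniform_lengths(rng, n_fragments, min(lo, hi), hi)
    prefix = id_prefix or f"{genome.id}_frag"
    out = []
    for i, L in enumerate(lengths):
        start = int(rng.integers(0, genome.length - L + 1))
        out.append(genome.slice(start, start + int(L), new_id=f"{prefix}{i:04d}"))
    return out


def generate_metagenome(
    models: Sequence[GenomeModel],
    n_per_model: int,
    length_range: tuple[int, int] = (1000, 20000),
    seed: int = 0,
    no_bin_models: Sequence[str] = (),
) -> SyntheticMetagenome:
    """Sample `n_per_model` contigs from each model with known origins.

    Models listed in `no_bin_models` are treated as taxa without a trained
    bin: their contigs enter the truth table's no-bin-available set, which
    is what specificity is measured on.
    """
    if not models:
        raise ValueError("at least one model is required")
    lo, hi = length_range
    if not 1 <= lo <= hi:
        raise ValueError(f"invalid length bounds [{lo}, {hi}]")
    withheld = set(no_bin_models)
    unknown = withheld - {m.model_id for m in models}
    if unknown:
        raise ValueError(f"no_bin_models not among the models: {sorted(unknown)}")
    root = np.random.SeedSequence(seed)
    per_model = root.spawn(len(models))
    records: list[SequenceRecord] = []
    labels: dict[str, str] = {}
    no_bin: set[str] = set()
    for model, child in zip(models, per_model):
        streams = child.spawn(n_per_model + 1)
        lengths = _log_uniform_lengths(
            np.random.default_rng(streams[0]), n_per_model, lo, hi
        )
        for i in range(n_per_model):
            rid = f"{model.model_id}_c{i:05d}"
            rng = np.random.default_rng(streams[i + 1])
            codes = _sample_codes(model, int(lengths[i]), rng)
            records.append(
                SequenceRecord(rid, _BASES[codes].tobytes().decode("ascii"))
            )
            if model.model_id in withheld:
                no_bin.add(rid)
            else:
                labels[rid] = model.model_id
    truth = TruthTable(labels=labels, no_bin=no_bin)
    params = {
        "n_models": len(models),
        "n_per_model": n_per_model,
        "length_range": (lo, hi),
        "seed": seed,
        "no_bin_models": sorted(withheld),
    }
    return SyntheticMetagenome(records=records, truth=truth, params=params)
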