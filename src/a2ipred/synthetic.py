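"""Synthetic labeled window datasets with controllable class separation.

The generator emulates the shape of an editing-site benchmark — two classes
of fixed-length (default 51 nt) RNA windows, each with the candidate A at
the central position, with class sizes defaulting to 125 positives and
119 negatives — while making the *signal* explicit and tunable: each window
is drawn from a first-order Markov chain over {A, C, G, U} whose transition
weights are tilted toward class-favored dinucleotides. Because the
dinucleotide composition is exactly what the PseDNC encoder measures, the
``separation`` knob directly controls how recoverable the labels are:
at 0 the classes are exchangeable, at 1 the bias maps apply at full
strength. The central position is overwritten with A after generation
(a slight distortion of the composition, accepted by design).

This is a statistical test harness, not a biological simulator: it imitates
no real editing motif or ADAR neighbor preference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .sequence_io import NucleotideSequence, SiteWindow, write_fasta

logger = logging.getLogger(__name__)

_BASES = "ACGU"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}

#: Default class biases: positives favor CG/GC steps, negatives AU/UA —
#: disjoint dinucleotide sets, so full separation is cleanly learnable.
DEFAULT_POS_BIAS: dict[str, float] = {"CG": 4.0, "GC": 4.0}
DEFAULT_NEG_BIAS: dict[str, float] = {"AU": 4.0, "UA": 4.0}


class SyntheticError(ValueError):
    pass


@dataclass(frozen=True)
class SyntheticDatasetSpec:
    """Parameters of one generated dataset.

    separation in [0, 1] interpolates each bias multiplier m geometrically
    (m ** separation), so separation = 0 makes both classes identical
    uniform chains and separation = 1 applies the bias maps at full
    strength.
    """

    n_pos: int = 125
    n_neg: int = 119
    window_length: int = 51
    pos_dinucleotide_bias: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_POS_BIAS)
    )
    neg_dinucleotide_bias: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_NEG_BIAS)
    )
    separation: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window_length % 2 == 0 or self.window_length < 3:
            raise SyntheticError(
                f"window_length must be odd and >= 3; got {self.window_length}"
            )
        if not 0.0 <= self.separation <= 1.0:
            raise SyntheticError(f"separation must be in [0, 1]; got {self.separation}")
        if self.n_pos < 0 or self.n_neg < 0:
            raise SyntheticError("class sizes must be non-negative")
        for bias in (self.pos_dinucleotide_bias, self.neg_dinucleotide_bias):
            if any(wt <= 0 for wt in bias.values()):
                raise SyntheticError("bias weights must be positive")


def _transition_matrix(bias: dict[str, float], separation: float) -> np.ndarray:
    """Row-stochastic 4x4 transition matrix tilted by the bias map."""
    weights = np.ones((4, 4))
    for dinuc, mult in bias.items():
        i, j = _BASE_INDEX[dinuc[0]], _BASE_INDEX[dinuc[1]]
        weights[i, j] = mult**separation
    return weights / weights.sum(axis=1, keepdims=True)


def _draw_window(
    rng: np.random.Generator, trans: np.ndarray, length: int
) -> str:
    states = np.empty(length, dtype=int)
    states[0] = rng.integers(4)
    for t in range(1, length):
        states[t] = rng.choice(4, p=trans[states[t - 1]])
    chars = [_BASES[s] for s in states]
    chars[length // 2] = "A"  # force the candidate adenosine at the center
    return "".join(chars)


def generate_dataset(
    spec: SyntheticDatasetSpec,
) -> tuple[list[SiteWindow], list[int]]:
    """Generate n_pos + n_neg labeled windows, reproducible from the seed.

    Returns (windows, labels) with labels +1 for the positive class.
    """
    rng = np.random.default_rng(spec.seed)
    pos_trans = _transition_matrix(spec.pos_dinucleotide_bias, spec.separation)
    neg_trans = _transition_matrix(spec.neg_dinucleotide_bias, spec.separation)
    center = spec.window_length // 2 + 1
    windows: list[SiteWindow] = []
    labels: list[int] = []
    for i in range(spec.n_pos):
        residues = _draw_window(rng, pos_trans, spec.window_length)
        windows.append(SiteWindow(f"pos_{i + 1}", center, residues))
        labels.append(1)
    for i in range(spec.n_neg):
        residues = _draw_window(rng, neg_trans, spec.window_length)
        windows.append(SiteWindow(f"neg_{i + 1}", center, residues))
        labels.append(-1)
    return windows, labels


def write_benchmark_like(
    spec: SyntheticDatasetSpec, directory: str | Path
) -> tuple[Path, Path]:
    """Materialize a generated dataset as two FASTA files (positive,
    negative), the shape an editing-site benchmark download takes."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    windows, labels = generate_dataset(spec)
    pos = [
        NucleotideSequence(w.source_id, w.residues)
        for w, y in zip(windows, labels)
        if y == 1
    ]
    neg = [
        NucleotideSequence(w.source_id, w.residues)
        for w, y in zip(windows, labels)
        if y == -1
    ]
    pos_path = directory / "positives.fasta"
    neg_path = directory / "negatives.fasta"
    if not pos:
        logger.warning("no positive windows generated; writing empty %s", pos_path)
    if not neg:
        logger.warning("no negative windows generated; writing empty %s", neg_path)
    write_fasta(pos, pos_path)
    write_fasta(neg, neg_path)
    return pos_path, neg_path
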