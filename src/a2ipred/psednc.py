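"""Pseudo dinucleotide composition (PseDNC) encoding.

A window of length L is represented by 16 + lambda components: the 16
dinucleotide frequencies f_u, followed by lambda "pseudo" components built
from tier correlation factors

    theta_j = (1 / (L - 1 - j)) * sum_i Theta(T_i, T_{i+j}),   j = 1..lambda,

where T_i is the dinucleotide starting at position i and Theta is the mean
squared difference of the six standardized physicochemical property values
of two dinucleotides. The final vector is

    d_u      = f_u / (sum_f + w * sum_theta)          for u = 1..16,
    d_{16+j} = w * theta_j / (sum_f + w * sum_theta)  for j = 1..lambda,

so the components are non-negative and sum to 1. The weight w balances
local composition against the global, order-dependent pseudo components;
lambda sets how many correlation tiers (sequence separations) are counted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from .properties import DINUC_INDEX, DINUCLEOTIDES, PropertyTable
from .sequence_io import SiteWindow

CountingMode = Literal["overlapping", "non_overlapping"]


class EncodingError(ValueError):
    pass


@dataclass(frozen=True)
class PseDNCConfig:
    """Encoding parameters.

    w : weight factor in [0, 1] for the pseudo components (default 0.3).
    lam : number of correlation tiers lambda >= 1 (default 4); must not
        exceed L - 2 for a window of length L, so every tier averages at
        least one dinucleotide pair.
    counting_mode : how the 16 frequencies are counted. ``overlapping``
        (default) counts all L-1 adjacent dinucleotides — the convention the
        correlation factors themselves use; ``non_overlapping`` counts
        disjoint pairs at positions 1-2, 3-4, ...
    """

    w: float = 0.3
    lam: int = 4
    counting_mode: CountingMode = "overlapping"

    def __post_init__(self) -> None:
        if not 0.0 <= self.w <= 1.0:
            raise EncodingError(f"weight w must be in [0, 1]; got {self.w}")
        if self.lam < 1:
            raise EncodingError(f"lambda must be >= 1; got {self.lam}")
        if self.counting_mode not in ("overlapping", "non_overlapping"):
            raise EncodingError(f"unknown counting mode {self.counting_mode!r}")

    @property
    def dimension(self) -> int:
        return 16 + self.lam

    def validate_for_length(self, window_length: int) -> None:
        if self.lam > window_length - 2:
            raise EncodingError(
                f"lambda={self.lam} too large for window length {window_length}; "
                f"need lambda <= L - 2 = {window_length - 2}"
            )


def _residues(window: SiteWindow | str) -> str:
    return window.residues if isinstance(window, SiteWindow) else window


def dinucleotide_frequencies(
    window: SiteWindow | str, mode: CountingMode = "overlapping"
) -> np.ndarray:
    """Normalized dinucleotide frequencies in fixed lexicographic order.

    Overlapping mode counts the L-1 adjacent dinucleotides; non-overlapping
    mode counts the floor(L/2) disjoint pairs. Either way the 16 entries
    sum to 1.
    """
    seq = _residues(window)
    if len(seq) < 2:
        raise EncodingError("need at least 2 residues to count dinucleotides")
    counts = np.zeros(16)
    if mode == "overlapping":
        for i in range(len(seq) - 1):
            counts[DINUC_INDEX[seq[i : i + 2]]] += 1
    elif mode == "non_overlapping":
        for i in range(0, len(seq) - 1, 2):
            counts[DINUC_INDEX[seq[i : i + 2]]] += 1
    else:
        raise EncodingError(f"unknown counting mode {mode!r}")
    return counts / counts.sum()


def _theta_matrix(table: PropertyTable) -> np.ndarray:
    """Precomputed 16 x 16 matrix of Theta(d1, d2) values."""
    z = table.values
    diff = z[:, None, :] - z[None, :, :]
    return np.mean(diff**2, axis=2)


def correlation_theta(
    dinuc1: str, dinuc2: str, table: PropertyTable
) -> float:
    """Structural dissimilarity Theta of two dinucleotides.

    The mean over the v=6 standardized properties of the squared value
    difference; zero for identical property rows.
    """
    if not table.standardized:
        raise EncodingError("correlation requires a standardized property table")
    d1 = table.row(dinuc1)
    d2 = table.row(dinuc2)
    return float(np.mean((d1 - d2) ** 2))


def tier_correlation(
    window: SiteWindow | str, j: int, table: PropertyTable
) -> float:
    """The j-tier correlation factor theta_j: mean Theta over all dinucleotide
    pairs separated by j positions along the window."""
    if not table.standardized:
        raise EncodingError("correlation requires a standardized property table")
    seq = _residues(window)
    L = len(seq)
    if not 1 <= j <= L - 2:
        raise EncodingError(
            f"tier j={j} invalid for length {L}; need 1 <= j <= L - 2"
        )
    theta_mat = _theta_matrix(table)
    idx = np.array([DINUC_INDEX[seq[i : i + 2]] for i in range(L - 1)])
    return float(np.mean(theta_mat[idx[: L - 1 - j], idx[j:]]))


def encode(
    window: SiteWindow | str,
    config: PseDNCConfig,
    table: PropertyTable,
) -> np.ndarray:
    """PseDNC feature vector of one window: 16 + lambda non-negative
    components summing to 1."""
    if not table.standardized:
        raise EncodingError("encode requires a standardized property table")
    seq = _residues(window)
    L = len(seq)
    config.validate_for_length(L)

    f = dinucleotide_frequencies(seq, config.counting_mode)

    theta_mat = _theta_matrix(table)
    idx = np.array([DINUC_INDEX[seq[i : i + 2]] for i in range(L - 1)])
    thetas = np.array(
        [np.mean(theta_mat[idx[: L - 1 - j], idx[j:]]) for j in range(1, config.lam + 1)]
    )

    denom = f.sum() + config.w * thetas.sum()
    vec = np.empty(16 + config.lam)
    vec[:16] = f / denom
    vec[16:] = config.w * thetas / denom
    return vec


def encode_batch(
    windows: Sequence[SiteWindow | str],
    config: PseDNCConfig,
    table: PropertyTable,
) -> np.ndarray:
    """Encode many windows into an (n, 16 + lambda) feature matrix."""
    if not windows:
        return np.empty((0, config.dimension))
    return np.vstack([encode(w, config, table) for w in windows])


FEATURE_NAMES_BASE = tuple(f"f_{d}" for d in DINUCLEOTIDES)


def feature_names(config: PseDNCConfig) -> tuple[str, ...]:
    return FEATURE_NAMES_BASE + tuple(
        f"theta_{j}" for j in range(1, config.lam + 1)
    )


def write_feature_table(
    path,
    ids: Sequence[str],
    features: np.ndarray,
    labels: Sequence[int] | None = None,
    config: PseDNCConfig | None = None,
) -> None:
    """Write features as tab-separated text: id, optional label, then one
    column per component."""
    with open(path, "w") as fh:
        header = ["id"]
        if labels is not None:
            header.append("label")
        if config is not None:
            header.extend(feature_names(config))
        else:
            header.extend(f"x{i}" for i in range(features.shape[1]))
        fh.write("\t".join(header) + "\n")
        for i, ident in enumerate(ids):
            row = [ident]
            if labels is not None:
                row.append(str(int(labels[i])))
            row.extend(f"{v:.12g}" for v in features[i])
            fh.write("\t".join(row) + "\n")


def write_libsvm(
    path, features: np.ndarray, labels: Iterable[int]
) -> None:
    """Write features in sparse libsvm format: ``label idx:val ...`` with
    1-based feature indices, zero entries omitted."""
    with open(path, "w") as fh:
        for label, row in zip(labels, features):
            cells = [str(int(label))]
            cells.extend(
                f"{i + 1}:{v:.12g}" for i, v in enumerate(row) if v != 0.0
            )
            fh.write(" ".join(cells) + "\n")
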