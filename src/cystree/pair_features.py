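"""523-dimension cysteine-pair encoding for supervised benchmarks.

Each candidate bond (c_i, c_j) of the query is encoded as:

* 520 dims — for each of the two cysteines, a 13-position window (6 left,
  6 right) of per-column amino-acid frequency profiles (20 dims each)
  from the family MSA; windows clipped by the sequence ends contribute
  zero blocks;
* 1 dim — the sequence separation ln|c_i - c_j|;
* 2 dims — the pair's relative order among the n oxidized cysteines,
  rank/n for each member (1-based ranks).

Only the encoder lives here; training a downstream regressor on the
resulting matrix is the consumer's business. A helper appends an extra
0/1 prediction dimension (giving 524) for stacking an unsupervised
predictor's output onto the vectors.
"""

from __future__ import annotations

import math

import numpy as np

from .alignment_io import AMINO_ACIDS, GAP_CHARS, AlignedFamily, QueryProtein

WINDOW = 6  # columns on each side of the central cysteine
WINDOW_LENGTH = 2 * WINDOW + 1
N_DIMS = 20 * 2 * WINDOW_LENGTH + 1 + 2  # 523

_AA_INDEX = {aa: k for k, aa in enumerate(AMINO_ACIDS)}


def column_profile(family: AlignedFamily, column: int) -> np.ndarray:
    """Amino-acid frequency profile of one alignment column.

    Gaps carry no mass: they are excluded from numerator and denominator.
    Non-standard residue codes (e.g. X) count toward the denominator but
    have no dimension of their own, so the 20 frequencies sum to <= 1.
    An all-gap column yields the zero vector.
    """
    if not 0 <= column < family.n_columns:
        raise IndexError(f"column {column} outside alignment of width {family.n_columns}")
    counts = np.zeros(20)
    total = 0
    for _, seq in family.rows:
        ch = seq[column].upper()
        if ch in GAP_CHARS:
            continue
        total += 1
        k = _AA_INDEX.get(ch)
        if k is not None:
            counts[k] += 1
    return counts / total if total else counts


def _position_to_column(family: AlignedFamily) -> list[int]:
    qrow = family.query_row
    return [col for col, ch in enumerate(qrow) if ch not in GAP_CHARS]


def _window_block(family: AlignedFamily, pos2col: list[int], center: int) -> np.ndarray:
    block = np.zeros((WINDOW_LENGTH, 20))
    for k, pos in enumerate(range(center - WINDOW, center + WINDOW + 1)):
        if 0 <= pos < len(pos2col):
            block[k] = column_profile(family, pos2col[pos])
    return block.ravel()


def encode_pair(family: AlignedFamily, query: QueryProtein, i: int, j: int) -> np.ndarray:
    """Feature vector for the candidate bond between oxidized cysteines i, j.

    ``i`` and ``j`` index ``query.oxidized_positions`` (i < j); the result
    has exactly :data:`N_DIMS` = 523 entries.
    """
    n = query.n_cysteines
    if not (0 <= i < j < n):
        raise ValueError(f"need 0 <= i < j < {n}, got i={i}, j={j}")
    pos2col = _position_to_column(family)
    ci, cj = query.oxidized_positions[i], query.oxidized_positions[j]
    parts = [
        _window_block(family, pos2col, ci),
        _window_block(family, pos2col, cj),
        np.array([math.log(abs(ci - cj))]),
        np.array([(i + 1) / n, (j + 1) / n]),
    ]
    vec = np.concatenate(parts)
    assert vec.shape == (N_DIMS,)
    return vec


def encode_all_pairs(family: AlignedFamily, query: QueryProtein) -> tuple[list[tuple[int, int]], np.ndarray]:
    """Encode all |C|(|C|-1)/2 candidate bonds; rows follow pair order."""
    n = query.n_cysteines
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    X = np.vstack([encode_pair(family, query, i, j) for i, j in pairs])
    return pairs, X


def append_prediction_bit(vectors: np.ndarray, bits: np.ndarray) -> np.ndarray:
    """Stack a 0/1 predicted-bond column onto pair vectors (523 -> 524)."""
    vectors = np.atleast_2d(vectors)
    bits = np.asarray(bits, dtype=float).reshape(-1, 1)
    if not np.all((bits == 0) | (bits == 1)):
        raise ValueError("prediction bits must be 0 or 1")
    if bits.shape[0] != vectors.shape[0]:
        raise ValueError("one bit per vector required")
    return np.hstack([vectors, bits])


def to_tsv(pairs: list[tuple[int, int]], X: np.ndarray, query: QueryProtein) -> str:
    """Feature matrix as TSV, one row per pair, 1-based residue positions."""
    header = ["residue_i", "residue_j"] + [f"f{k}" for k in range(X.shape[1])]
    lines = ["\t".join(header)]
    for (i, j), row in zip(pairs, X):
        ci = query.oxidized_positions[i] + 1
        cj = query.oxidized_positions[j] + 1
        lines.append("\t".join([str(ci), str(cj)] + [f"{v:.6g}" for v in row]))
    return "\n".join(lines) + "\n"
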