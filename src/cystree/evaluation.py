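"""Rb / Qp scoring and closed-form random baselines.

Rb is the fraction of correctly predicted bonds among all observed bonds;
Qp is the fraction of proteins whose whole connectivity is predicted
exactly. Against a uniform random perfect matching on 2d cysteines the
expectations are Rb = 1/(2d-1) (each bond's partner is one of 2d-1
equally likely choices) and Qp = 1/(2d-1)!! (one matching out of all
(2d-1)!! of them).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import factorial2

from .matching import BondPattern


@dataclass(frozen=True)
class ScoredRecord:
    protein_id: str
    truth: BondPattern
    predicted: BondPattern

    def __post_init__(self) -> None:
        if self.truth.n != self.predicted.n:
            raise ValueError(
                f"{self.protein_id}: truth covers {self.truth.n} cysteines, "
                f"prediction {self.predicted.n}"
            )

    @property
    def d(self) -> int:
        return self.truth.d

    @property
    def correct_bonds(self) -> int:
        return len(set(self.truth.pairs) & set(self.predicted.pairs))

    @property
    def exact(self) -> bool:
        return self.truth.pairs == self.predicted.pairs


def score_rb(records: list[ScoredRecord], average: str = "micro") -> float:
    """Correctly predicted bonds over observed bonds.

    ``micro`` (default) pools bonds across proteins; ``macro`` averages
    the per-protein fractions.
    """
    if not records:
        raise ValueError("empty record set")
    if average == "micro":
        return sum(r.correct_bonds for r in records) / sum(r.d for r in records)
    if average == "macro":
        return float(np.mean([r.correct_bonds / r.d for r in records]))
    raise ValueError(f"unknown average {average!r}")


def score_qp(records: list[ScoredRecord], folds: list[int] | None = None) -> float:
    """Fraction of proteins predicted exactly.

    With ``folds`` (one group index per record) Qp is computed per fold
    and the fold scores averaged — the grouped-subset convention, which
    can deviate from the whole-dataset fraction when folds are small.
    """
    if not records:
        raise ValueError("empty record set")
    exact = np.array([r.exact for r in records], dtype=float)
    if folds is None:
        return float(exact.mean())
    if len(folds) != len(records):
        raise ValueError("folds must assign one group per record")
    df = pd.DataFrame({"fold": folds, "exact": exact})
    return float(df.groupby("fold")["exact"].mean().mean())


def random_baseline(d: int) -> tuple[float, float]:
    """Expected (Rb, Qp) of a uniform random matching, as percentages."""
    if d < 1:
        raise ValueError("d must be >= 1")
    rb = 100.0 / (2 * d - 1)
    qp = 100.0 / float(factorial2(2 * d - 1))
    return rb, qp


def report_table(records: list[ScoredRecord]) -> pd.DataFrame:
    """Per-bond-count Rb/Qp table with the random baseline, percentages."""
    if not records:
        raise ValueError("empty record set")
    rows = []
    for d in sorted({r.d for r in records}):
        sub = [r for r in records if r.d == d]
        rb_rand, qp_rand = random_baseline(d)
        rows.append(
            {
                "bonds": d,
                "proteins": len(sub),
                "Rb": 100.0 * score_rb(sub),
                "Qp": 100.0 * score_qp(sub),
                "Rb_random": rb_rand,
                "Qp_random": qp_rand,
            }
        )
    return pd.DataFrame(rows)


def read_bonds_tsv(path: str | Path) -> dict[str, list[tuple[int, int]]]:
    """Read ``protein_id  residue_i  residue_j`` rows (1-based positions)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["protein_id", "residue_i", "residue_j"])
    out: dict[str, list[tuple[int, int]]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.protein_id), []).append(
            tuple(sorted((int(row.residue_i), int(row.residue_j))))
        )
    return out


def write_bonds_tsv(path: str | Path, bonds: dict[str, list[tuple[int, int]]]) -> None:
    with open(path, "w") as fh:
        for pid in bonds:
            for i, j in sorted(bonds[pid]):
                fh.write(f"{pid}\t{i}\t{j}\n")


def records_from_position_bonds(
    truths: dict[str, list[tuple[int, int]]],
    predictions: dict[str, list[tuple[int, int]]],
) -> list[ScoredRecord]:
    """Build scored records from residue-position bond lists.

    Positions are re-indexed per protein to 0..n-1 by sorted order so the
    BondPattern coverage invariant applies; truth and prediction must name
    the same proteins and cysteines.
    """
    missing = sorted(set(truths) ^ set(predictions))
    if missing:
        raise ValueError(f"protein ids not shared by truth and prediction: {missing}")
    records = []
    for pid, true_bonds in truths.items():
        pred_bonds = predictions[pid]
        cys = sorted({p for b in true_bonds for p in b})
        if sorted({p for b in pred_bonds for p in b}) != cys:
            raise ValueError(f"{pid}: truth and prediction cover different cysteines")
        idx = {p: k for k, p in enumerate(cys)}
        records.append(
            ScoredRecord(
                protein_id=pid,
                truth=BondPattern(tuple((idx[a], idx[b]) for a, b in true_bonds)),
                predicted=BondPattern(tuple((idx[a], idx[b]) for a, b in pred_bonds)),
            )
        )
    return records
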