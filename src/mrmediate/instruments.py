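"""Instrument selection: significance thresholding, LD clumping, F filtering.

A valid genetic instrument must be robustly associated with the exposure
(p-value threshold, F-statistic ≥ 10) and approximately independent of the
other instruments (LD clumping: greedy pruning of correlated SNPs within a
genomic window, keeping the most significant representative of each clump).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .sumstats import InputError, SumstatRecord

logger = logging.getLogger("mrmediate")


@dataclass
class LDMatrix:
    """Pairwise squared correlations (r²) between SNPs.

    ``r2`` is symmetric with unit diagonal; ``positions`` are base-pair
    coordinates aligned to ``snp_ids`` and used for window checks.
    """

    snp_ids: list[str]
    r2: np.ndarray
    positions: list[int]
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        n = len(self.snp_ids)
        if self.r2.shape != (n, n):
            raise InputError("LD matrix shape does not match snp_ids")
        if len(self.positions) != n:
            raise InputError("LD positions do not match snp_ids")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def validate(self) -> None:
        """Raise InputError if the matrix is asymmetric or ill-ranged."""
        if not np.allclose(self.r2, self.r2.T, atol=1e-8):
            raise InputError("LD matrix is not symmetric")
        if not np.allclose(np.diag(self.r2), 1.0, atol=1e-8):
            raise InputError("LD matrix diagonal is not 1")
        if self.r2.min() < -1e-8 or self.r2.max() > 1 + 1e-8:
            raise InputError("LD r2 values outside [0, 1]")

    def lookup(self, a: str, b: str) -> float | None:
        ia, ib = self._index.get(a), self._index.get(b)
        if ia is None or ib is None:
            return None
        return float(self.r2[ia, ib])

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def read(cls, path: str | Path, positions: dict[str, int] | None = None) -> "LDMatrix":
        """Read LD from a square TSV (snp_ids as header row & first column)
        or a long-format triplet file with columns snp_a, snp_b, r2."""
        path = Path(path)
        df = pd.read_csv(path, sep="\t")
        if set(df.columns[:3]) >= {"snp_a", "snp_b", "r2"}:
            ids = sorted(set(df["snp_a"]) | set(df["snp_b"]))
            ix = {s: i for i, s in enumerate(ids)}
            r2 = np.eye(len(ids))
            for row in df.itertuples(index=False):
                i, j = ix[row.snp_a], ix[row.snp_b]
                r2[i, j] = r2[j, i] = row.r2
        else:
            df = df.set_index(df.columns[0])
            ids = list(df.columns)
            r2 = df.to_numpy(dtype=float)
        pos = [int((positions or {}).get(s, 0)) for s in ids]
        return cls(snp_ids=ids, r2=r2, positions=pos)

    def write(self, path: str | Path) -> None:
        df = pd.DataFrame(self.r2, columns=self.snp_ids)
        df.insert(0, "snp_id", self.snp_ids)
        df.to_csv(path, sep="\t", index=False)


@dataclass
class InstrumentDiagnostics:
    """Per-SNP and mean instrument-strength F statistics."""

    per_snp_f: dict[str, float]
    mean_f: float
    n_selected: int
    threshold_used: float


def select_by_pvalue(
    records: Sequence[SumstatRecord], threshold: float
) -> list[SumstatRecord]:
    """Keep records with pvalue strictly below ``threshold`` (order kept)."""
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"p-value threshold must be in (0, 1), got {threshold}")
    kept = [r for r in records if r.pvalue < threshold]
    if not kept:
        logger.info("select_by_pvalue: no SNPs below %g", threshold)
    return kept


def clump(
    records: Sequence[SumstatRecord],
    ld: LDMatrix,
    r2_threshold: float = 0.01,
    window_kb: int = 10_000,
) -> list[SumstatRecord]:
    """Greedy LD clumping, PLINK-style.

    Sort by ascending p-value (ties broken by snp_id); repeatedly accept the
    most significant remaining SNP and discard all unaccepted SNPs on the
    same chromosome within ``window_kb`` kilobases whose r² with it is at
    least ``r2_threshold``.  SNPs absent from the LD matrix are retained
    with a warning (permissive clumping).  Returns accepted SNPs in genomic
    order.
    """
    ld.validate()
    missing = [r.snp_id for r in records if r.snp_id not in ld._index]
    if missing:
        logger.warning("clump: %d SNP(s) missing from LD matrix, retained: %s",
                       len(missing), ", ".join(missing[:5]))
    order = sorted(records, key=lambda r: (r.pvalue, r.snp_id))
    accepted: list[SumstatRecord] = []
    removed: set[str] = set()
    for rec in order:
        if rec.snp_id in removed:
            continue
        accepted.append(rec)
        for other in order:
            if other.snp_id == rec.snp_id or other.snp_id in removed:
                continue
            if other in accepted:
                continue
            if other.chrom != rec.chrom:
                continue
            if abs(other.pos - rec.pos) > window_kb * 1000:
                continue
            r2 = ld.lookup(rec.snp_id, other.snp_id)
            if r2 is not None and r2 >= r2_threshold:
                removed.add(other.snp_id)
    accepted.sort(key=lambda r: (r.chrom, r.pos, r.snp_id))
    return accepted


def f_statistics(
    records: Sequence[SumstatRecord],
    min_f: float = 10.0,
    method: str = "beta_se",
) -> tuple[list[SumstatRecord], InstrumentDiagnostics]:
    """Filter weak instruments by per-SNP F-statistic.

    ``method="beta_se"`` uses the summary-data approximation F = (β/se)².
    ``method="r2"`` uses F = R²(n−2)/(1−R²) with R² = 2·maf·(1−maf)·β²,
    which needs eaf and n.
    """
    per_f: dict[str, float] = {}
    retained: list[SumstatRecord] = []
    for rec in records:
        if method == "beta_se":
            f = (rec.beta / rec.se) ** 2
        elif method == "r2":
            r2 = 2.0 * rec.maf * (1.0 - rec.maf) * rec.beta**2
            r2 = min(r2, 1.0 - 1e-12)
            f = r2 * (rec.n - 2) / (1.0 - r2)
        else:
            raise ValueError(f"unknown F-statistic method {method!r}")
        if f >= min_f:
            per_f[rec.snp_id] = f
            retained.append(rec)
    diag = InstrumentDiagnostics(
        per_snp_f=per_f,
        mean_f=float(np.mean(list(per_f.values()))) if per_f else float("nan"),
        n_selected=len(retained),
        threshold_used=min_f,
    )
    return retained, diag
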