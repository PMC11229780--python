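"""GWAS summary-statistic records, file I/O, and allele harmonization.

Summary statistics are the universal currency of two-sample Mendelian
randomization: one row per SNP carrying the per-allele effect estimate
(beta), its standard error, the effect-allele frequency and the sample
size.  Before any causal estimate can be formed, the exposure and outcome
files must be *harmonized* so that every retained SNP's effect is
expressed with respect to the same effect allele in both traits.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger("mrmediate")

VALID_ALLELES = frozenset("ACGT")
#: complementary-strand base pairing
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: canonical field names expected by the rest of the pipeline
SUMSTAT_FIELDS = (
    "snp_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pvalue", "n",
)


class InputError(ValueError):
    """Malformed or empty input data."""


class ConfigurationError(ValueError):
    """Invalid configuration, e.g. a missing mandatory column."""


class HarmonizationError(ValueError):
    """No SNP pairs survived harmonization."""


@dataclass(frozen=True)
class SumstatRecord:
    """One SNP's association summary for one trait.

    ``beta`` is the per-allele effect of ``effect_allele`` on the trait
    (linear scale for quantitative traits, linear-probability or log-odds
    for binary ones); ``se`` its standard error; ``eaf`` the effect-allele
    frequency; ``n`` the GWAS sample size.
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pvalue: float
    n: int

    def validate(self) -> str | None:
        """Return a reason string if any invariant is violated, else None."""
        if self.effect_allele not in VALID_ALLELES or self.other_allele not in VALID_ALLELES:
            return "invalid-allele"
        if self.effect_allele == self.other_allele:
            return "identical-alleles"
        if not self.se > 0:
            return "nonpositive-se"
        if not 0.0 <= self.eaf <= 1.0:
            return "eaf-out-of-range"
        if not 0.0 < self.pvalue <= 1.0:
            return "pvalue-out-of-range"
        if self.n <= 0:
            return "nonpositive-n"
        return None

    @property
    def maf(self) -> float:
        """Minor-allele frequency, min(eaf, 1 - eaf)."""
        return min(self.eaf, 1.0 - self.eaf)

    @property
    def is_palindromic(self) -> bool:
        """True for A/T and C/G variants, whose strand is ambiguous."""
        return _COMPLEMENT[self.effect_allele] == self.other_allele


@dataclass(frozen=True)
class HarmonizedPair:
    """Allele-aligned exposure/outcome effect pair for one SNP."""

    snp_id: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: float
    se_outcome: float
    eaf: float
    n_exposure: int
    n_outcome: int


@dataclass
class HarmonizedInstrumentSet:
    """Exposure/outcome effect pairs sharing one allele orientation.

    ``dropped`` records every matched SNP that could not be aligned,
    as ``(snp_id, reason)`` tuples, for audit.
    """

    exposure_name: str
    outcome_name: str
    records: list[HarmonizedPair]
    dropped: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_snp(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.records])

    def dropped_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dropped, columns=["snp_id", "reason"])

    def write_tsv(self, path: str | Path) -> None:
        """Write aligned pairs as TSV, with the audit table alongside."""
        path = Path(path)
        self.to_frame().to_csv(path, sep="\t", index=False)
        audit = path.with_name(path.stem + ".dropped.tsv")
        self.dropped_frame().to_csv(audit, sep="\t", index=False)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_NUMERIC = {"pos": int, "eaf": float, "beta": float, "se": float,
            "pvalue": float, "n": int}


def read_sumstats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> list[SumstatRecord]:
    """Read a delimited summary-statistics file into validated records.

    Parameters
    ----------
    path
        TSV or CSV file (delimiter inferred from the extension;
        ``.gz`` handled transparently).
    column_map
        Mapping from canonical field names (:data:`SUMSTAT_FIELDS`) to the
        column names used in the file.  Omitted fields are assumed to use
        the canonical name.

    Rows violating record invariants (se ≤ 0, eaf outside [0, 1], invalid
    alleles, ...) are dropped with a logged count.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"summary-statistics file not found: {path}")
    name = path.name[:-3] if path.name.endswith(".gz") else path.name
    sep = "," if name.endswith(".csv") else "\t"
    try:
        df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise InputError(f"empty summary-statistics file: {path}") from exc
    if df.empty:
        raise InputError(f"no data rows in summary-statistics file: {path}")

    cmap = dict(column_map or {})
    missing = [f for f in SUMSTAT_FIELDS if cmap.get(f, f) not in df.columns]
    if missing:
        raise ConfigurationError(
            f"mandatory column(s) missing from {path.name}: "
            + ", ".join(f"{f} (mapped to {cmap.get(f, f)!r})" for f in missing)
        )
    df = df.rename(columns={v: k for k, v in cmap.items()})

    records: list[SumstatRecord] = []
    drop_reasons: dict[str, int] = {}
    for row in df.itertuples(index=False):
        d = {f: getattr(row, f) for f in SUMSTAT_FIELDS}
        try:
            for f, conv in _NUMERIC.items():
                d[f] = conv(d[f])
        except (TypeError, ValueError):
            drop_reasons["unparseable-numeric"] = drop_reasons.get("unparseable-numeric", 0) + 1
            continue
        rec = SumstatRecord(
            snp_id=str(d["snp_id"]), chrom=str(d["chrom"]), pos=d["pos"],
            effect_allele=str(d["effect_allele"]).upper(),
            other_allele=str(d["other_allele"]).upper(),
            eaf=d["eaf"], beta=d["beta"], se=d["se"],
            pvalue=d["pvalue"], n=d["n"],
        )
        reason = rec.validate()
        if reason is None:
            records.append(rec)
        else:
            drop_reasons[reason] = drop_reasons.get(reason, 0) + 1
    if drop_reasons:
        logger.warning(
            "%s: dropped %d invalid row(s): %s", path.name,
            sum(drop_reasons.values()),
            ", ".join(f"{k}={v}" for k, v in sorted(drop_reasons.items())),
        )
    return records


def write_sumstats(records: Iterable[SumstatRecord], path: str | Path) -> None:
    """Write records as a canonical TSV (gzip if the path ends in .gz)."""
    df = pd.DataFrame([vars(r) for r in records], columns=SUMSTAT_FIELDS)
    path = Path(path)
    # %.17g round-trips IEEE doubles exactly
    if path.name.endswith(".gz"):
        with gzip.open(path, "wt") as fh:
            df.to_csv(fh, sep="\t", index=False, float_format="%.17g")
    else:
        df.to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Harmonization
# ---------------------------------------------------------------------------

def _dedupe(records: Sequence[SumstatRecord]) -> dict[str, SumstatRecord]:
    """Index by snp_id, keeping the lowest p-value among duplicates."""
    best: dict[str, SumstatRecord] = {}
    for rec in records:
        prev = best.get(rec.snp_id)
        if prev is None or rec.pvalue < prev.pvalue:
            best[rec.snp_id] = rec
    return best


def harmonize(
    exposure: Sequence[SumstatRecord],
    outcome: Sequence[SumstatRecord],
    palindrome_maf_cutoff: float = 0.3,
    exposure_name: str = "exposure",
    outcome_name: str = "outcome",
) -> HarmonizedInstrumentSet:
    """Align outcome effects to the exposure's effect alleles.

    For each SNP shared by ``exposure`` and ``outcome``:

    * same allele orientation — kept as-is;
    * swapped effect/other alleles — outcome beta negated and its eaf
      complemented;
    * palindromic (A/T or C/G) with MAF > ``palindrome_maf_cutoff`` —
      dropped as ``"palindromic-ambiguous"`` (frequency cannot resolve the
      strand for intermediate-frequency variants);
    * palindromic with MAF ≤ cutoff — aligned by comparing each trait's
      eaf to 0.5;
    * incompatible allele sets — dropped as ``"allele-mismatch"``.

    SNPs present on only one side are dropped as ``"unmatched"``.
    Duplicate snp_ids keep the record with the lowest p-value.
    """
    if not exposure or not outcome:
        raise InputError("harmonize requires nonempty exposure and outcome record lists")
    exp_ix = _dedupe(exposure)
    out_ix = _dedupe(outcome)

    records: list[HarmonizedPair] = []
    dropped: list[tuple[str, str]] = []
    for snp_id in exp_ix:
        if snp_id not in out_ix:
            dropped.append((snp_id, "unmatched"))
    for snp_id in out_ix:
        if snp_id not in exp_ix:
            dropped.append((snp_id, "unmatched"))

    for snp_id, e in exp_ix.items():
        o = out_ix.get(snp_id)
        if o is None:
            continue
        if e.is_palindromic and o.is_palindromic:
            if e.maf > palindrome_maf_cutoff:
                dropped.append((snp_id, "palindromic-ambiguous"))
                continue
            # allele letters are uninformative across strands; the side of
            # 0.5 each eaf falls on identifies the shared allele
            flip = (e.eaf > 0.5) != (o.eaf > 0.5)
        elif {e.effect_allele, e.other_allele} == {o.effect_allele, o.other_allele}:
            flip = e.effect_allele != o.effect_allele
        else:
            dropped.append((snp_id, "allele-mismatch"))
            continue
        beta_o = -o.beta if flip else o.beta
        records.append(HarmonizedPair(
            snp_id=snp_id,
            beta_exposure=e.beta, se_exposure=e.se,
            beta_outcome=beta_o, se_outcome=o.se,
            eaf=e.eaf,
            n_exposure=e.n, n_outcome=o.n,
        ))

    if not records:
        reasons = [r for _, r in dropped]
        dominant = max(set(reasons), key=reasons.count) if reasons else "no-shared-snps"
        raise HarmonizationError(
            f"no SNP pairs retained between {exposure_name} and {outcome_name} "
            f"(dominant drop reason: {dominant})"
        )
    records.sort(key=lambda r: r.snp_id)
    return HarmonizedInstrumentSet(
        exposure_name=exposure_name, outcome_name=outcome_name,
        records=records, dropped=dropped,
    )
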