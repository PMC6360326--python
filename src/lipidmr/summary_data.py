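"""GWAS summary-statistics data model, table I/O and allele harmonization.

Two-sample Mendelian randomization pairs per-SNP association results from an
exposure GWAS (here: a blood lipid, effects in per-SD units) with results for
the same SNPs from an outcome GWAS (here: ALS, effects in log-odds). Before
any estimator can run, the two sources must be put on a common effect-allele
orientation: strand flips are resolved by complementing alleles, allele swaps
by negating the outcome effect, and palindromic (A/T, C/G) SNPs — whose
orientation cannot be determined from alleles alone — are resolved or dropped
using allele frequencies.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from scipy.stats import norm

from .exceptions import ConfigurationError, EmptyInputError, EmptySetError

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
#: canonical column names for the tabular format
STANDARD_COLUMNS = {
    "snp_id": "SNP",
    "chrom": "CHR",
    "pos": "POS",
    "effect_allele": "EA",
    "other_allele": "OA",
    "eaf": "EAF",
    "beta": "BETA",
    "se": "SE",
    "pvalue": "P",
    "n": "N",
}
MANDATORY_FIELDS = ("snp_id", "effect_allele", "other_allele", "beta", "se", "pvalue")

#: relative tolerance for the beta/se/p consistency check, on the -log10 scale;
#: published tables round aggressively, so this is deliberately loose.
P_CONSISTENCY_RTOL = 0.10


@dataclass(frozen=True)
class GwasRecord:
    """One SNP's marginal association summary for a single trait.

    ``beta`` is in per-SD units for quantitative exposures and in log-odds
    for a binary outcome; ``eaf`` is the effect-allele frequency.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    chrom: str | None = None
    pos: int | None = None
    eaf: float | None = None
    n: int | None = None

    def validate(self) -> None:
        """Raise ``ValueError`` on any hard invariant violation."""
        if self.effect_allele not in VALID_ALLELES:
            raise ValueError(f"invalid effect allele {self.effect_allele!r}")
        if self.other_allele not in VALID_ALLELES:
            raise ValueError(f"invalid other allele {self.other_allele!r}")
        if self.effect_allele == self.other_allele:
            raise ValueError("effect and other allele are identical")
        if not self.se > 0:
            raise ValueError(f"se must be positive, got {self.se}")
        if not (0 < self.pvalue <= 1):
            raise ValueError(f"pvalue must lie in (0, 1], got {self.pvalue}")
        if self.eaf is not None and not (0 < self.eaf < 1):
            raise ValueError(f"eaf must lie in (0, 1), got {self.eaf}")
        if self.pos is not None and self.pos < 1:
            raise ValueError(f"pos must be a positive 1-based coordinate, got {self.pos}")
        if self.n is not None and self.n < 1:
            raise ValueError(f"n must be positive, got {self.n}")

    def pvalue_consistent(self, rtol: float = P_CONSISTENCY_RTOL) -> bool:
        """Check the reported p against the two-sided normal p of beta/se.

        Comparison is relative on the -log10 scale so that heavily rounded
        published p-values are not spuriously flagged.
        """
        z = abs(self.beta) / self.se
        expected = 2.0 * norm.sf(z)
        if expected <= 0:  # beyond float underflow; only tiny p is consistent
            return self.pvalue < 1e-300
        lo_obs = -math.log10(self.pvalue)
        lo_exp = -math.log10(expected)
        if lo_exp == 0 and lo_obs == 0:
            return True
        scale = max(abs(lo_exp), 1.0)
        return abs(lo_obs - lo_exp) <= rtol * scale

    def is_palindromic(self) -> bool:
        return COMPLEMENT[self.effect_allele] == self.other_allele


@dataclass(frozen=True)
class HarmonizedInstrument:
    """One SNP's paired exposure and outcome effects on a common effect allele."""

    snp_id: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: float
    se_outcome: float
    exposure_p: float
    outcome_p: float
    flipped: bool = False
    eaf: float | None = None
    n_exposure: int | None = None
    n_outcome: int | None = None


@dataclass
class InstrumentSet:
    """Named collection of harmonized instruments for one exposure-outcome pair."""

    exposure_name: str
    outcome_name: str
    instruments: list[HarmonizedInstrument]
    population: str = ""
    sd_unit: float | None = None  # exposure SD in mg/dL, for unit conversion

    def __post_init__(self) -> None:
        ids = [inst.snp_id for inst in self.instruments]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate snp_id in InstrumentSet")

    def __len__(self) -> int:
        return len(self.instruments)

    def __iter__(self):
        return iter(self.instruments)

    @property
    def snp_ids(self) -> list[str]:
        return [inst.snp_id for inst in self.instruments]

    def subset(self, snp_ids: Iterable[str]) -> "InstrumentSet":
        """Restrict to the given SNPs, preserving order."""
        keep = set(snp_ids)
        return replace(
            self, instruments=[i for i in self.instruments if i.snp_id in keep]
        )

    def drop(self, snp_ids: Iterable[str]) -> "InstrumentSet":
        """Remove the given SNPs, preserving order."""
        out = set(snp_ids)
        return replace(
            self, instruments=[i for i in self.instruments if i.snp_id not in out]
        )


@dataclass
class ReadReport:
    """Outcome of parsing a summary table: records plus row-level problems."""

    records: list[GwasRecord] = field(default_factory=list)
    rejected: list[tuple[int, str]] = field(default_factory=list)  # (row, reason)
    flagged: list[tuple[int, str]] = field(default_factory=list)  # kept but suspect

    @property
    def warnings(self) -> list[str]:
        return [f"row {row}: {reason}" for row, reason in self.rejected + self.flagged]


def _sniff_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def _parse_optional_float(text: str | None) -> float | None:
    if text is None or text.strip() in ("", "NA", "NaN", "nan", "."):
        return None
    return float(text)


def read_summary_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> ReadReport:
    """Read a tab- or comma-delimited GWAS summary table.

    Parameters
    ----------
    path
        Delimited text file with a header row.
    column_map
        Optional mapping from standard field name (``snp_id`` ... ``n``) to
        the source file's column header; defaults to the standard names
        (SNP, CHR, POS, EA, OA, EAF, BETA, SE, P, N).

    Returns
    -------
    ReadReport
        ``records`` holds one :class:`GwasRecord` per parseable row in input
        order; ``rejected`` and ``flagged`` report problems with 1-based data
        row numbers. Rows violating hard invariants (e.g. se ≤ 0) are
        rejected; rows whose p-value disagrees with the normal p of beta/se
        are kept but flagged.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"summary table not found: {path}")
    with path.open(newline="") as fh:
        first = fh.readline()
        if not first.strip():
            raise EmptyInputError(f"empty summary table: {path}")
        delim = _sniff_delimiter(first)
        fh.seek(0)
        reader = csv.DictReader(fh, delimiter=delim)
        columns = {k: v for k, v in STANDARD_COLUMNS.items()}
        if column_map:
            columns.update(column_map)
        fieldnames = reader.fieldnames or []
        for f in MANDATORY_FIELDS:
            if columns[f] not in fieldnames:
                raise ConfigurationError(
                    f"mandatory column {columns[f]!r} (field {f}) missing from {path}"
                )
        report = ReadReport()
        nrows = 0
        for rownum, row in enumerate(reader, start=1):
            nrows += 1
            try:
                rec = GwasRecord(
                    snp_id=row[columns["snp_id"]].strip(),
                    chrom=(row.get(columns["chrom"]) or "").strip() or None,
                    pos=(
                        int(float(row[columns["pos"]]))
                        if columns["pos"] in row and row[columns["pos"]].strip()
                        else None
                    ),
                    effect_allele=row[columns["effect_allele"]].strip().upper(),
                    other_allele=row[columns["other_allele"]].strip().upper(),
                    eaf=_parse_optional_float(row.get(columns["eaf"])),
                    beta=float(row[columns["beta"]]),
                    se=float(row[columns["se"]]),
                    pvalue=float(row[columns["pvalue"]]),
                    n=(
                        int(float(row[columns["n"]]))
                        if columns["n"] in row and (row[columns["n"]] or "").strip()
                        else None
                    ),
                )
                rec.validate()
            except (ValueError, KeyError) as exc:
                report.rejected.append((rownum, str(exc)))
                logger.warning("row %d rejected: %s", rownum, exc)
                continue
            if not rec.pvalue_consistent():
                msg = (
                    f"pvalue {rec.pvalue:g} inconsistent with beta/se "
                    f"(z={rec.beta / rec.se:.3g})"
                )
                report.flagged.append((rownum, msg))
                logger.warning("row %d flagged: %s", rownum, msg)
            report.records.append(rec)
        if nrows == 0:
            raise EmptyInputError(f"summary table has a header but no rows: {path}")
    return report


def write_summary_table(
    records: Sequence[GwasRecord], path: str | Path, delimiter: str = "\t"
) -> None:
    """Write records in the standard column layout (full float precision)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(list(STANDARD_COLUMNS.values()))
        for r in records:
            writer.writerow(
                [
                    r.snp_id,
                    r.chrom if r.chrom is not None else "NA",
                    r.pos if r.pos is not None else "NA",
                    r.effect_allele,
                    r.other_allele,
                    repr(r.eaf) if r.eaf is not None else "NA",
                    repr(r.beta),
                    repr(r.se),
                    repr(r.pvalue),
                    r.n if r.n is not None else "NA",
                ]
            )


def _match_orientation(
    exp: GwasRecord, out: GwasRecord
) -> tuple[bool, bool] | None:
    """Return (flipped, strand_complemented) or None if irreconcilable.

    ``flipped`` means the outcome's effect allele is the exposure's other
    allele, so the outcome beta (and eaf) must be inverted.
    """
    e_ea, e_oa = exp.effect_allele, exp.other_allele
    o_ea, o_oa = out.effect_allele, out.other_allele
    if (o_ea, o_oa) == (e_ea, e_oa):
        return False, False
    if (o_ea, o_oa) == (e_oa, e_ea):
        return True, False
    c_ea, c_oa = COMPLEMENT[o_ea], COMPLEMENT[o_oa]
    if (c_ea, c_oa) == (e_ea, e_oa):
        return False, True
    if (c_ea, c_oa) == (e_oa, e_ea):
        return True, True
    return None


def harmonize(
    exposure: Sequence[GwasRecord],
    outcome: Sequence[GwasRecord],
    palindrome_policy: str = "drop_ambiguous",
    eaf_ambiguity_band: float = 0.42,
    exposure_name: str = "exposure",
    outcome_name: str = "outcome",
    population: str = "",
    sd_unit: float | None = None,
) -> InstrumentSet:
    """Pair exposure instruments with outcome records on a shared effect allele.

    Matching is by ``snp_id`` only (the two GWAS may use different genome
    builds, so chrom/pos disagreement is logged, not fatal). SNPs absent from
    the outcome table are dropped — no proxy search. When the outcome's
    alleles are swapped relative to the exposure, the outcome beta is negated
    and ``flipped=True``; when they are the strand complement they are
    complemented first.

    Palindromic SNPs (A/T or C/G) carry no strand information in their
    alleles. Policy ``drop_ambiguous`` (default) drops those whose eaf on
    either side lies inside ``[band, 1-band]`` or is missing, and uses eaf
    agreement to orient the rest; ``keep`` assumes both GWAS report the same
    strand; ``drop_all`` discards every palindrome.
    """
    if palindrome_policy not in ("drop_ambiguous", "keep", "drop_all"):
        raise ConfigurationError(f"unknown palindrome policy {palindrome_policy!r}")
    out_by_id = {r.snp_id: r for r in outcome}
    instruments: list[HarmonizedInstrument] = []
    for exp in exposure:
        out = out_by_id.get(exp.snp_id)
        if out is None:
            logger.info("harmonize: %s absent from outcome table, dropped", exp.snp_id)
            continue
        if (
            exp.chrom is not None
            and out.chrom is not None
            and (exp.chrom != out.chrom or exp.pos != out.pos)
        ):
            logger.warning(
                "harmonize: %s position disagrees between sources "
                "(%s:%s vs %s:%s); matched by id",
                exp.snp_id, exp.chrom, exp.pos, out.chrom, out.pos,
            )
        if exp.is_palindromic():
            if palindrome_policy == "drop_all":
                logger.info("harmonize: %s palindromic, dropped (drop_all)", exp.snp_id)
                continue
            if palindrome_policy == "drop_ambiguous":
                band = eaf_ambiguity_band
                eafs = (exp.eaf, out.eaf)
                if any(e is None for e in eafs) or any(
                    band <= e <= 1 - band for e in eafs if e is not None
                ):
                    logger.info(
                        "harmonize: %s palindromic with ambiguous/missing eaf, dropped",
                        exp.snp_id,
                    )
                    continue
                # frequencies are informative: flip when they sit on opposite
                # sides of 0.5
                flipped = (exp.eaf < 0.5) != (out.eaf < 0.5)
            else:
                # keep: trust that both report the same strand
                orient = _match_orientation(exp, out)
                flipped = orient[0] if orient is not None else False
        else:
            orient = _match_orientation(exp, out)
            if orient is None:
                logger.warning(
                    "harmonize: %s alleles irreconcilable (%s/%s vs %s/%s), dropped",
                    exp.snp_id,
                    exp.effect_allele, exp.other_allele,
                    out.effect_allele, out.other_allele,
                )
                continue
            flipped = orient[0]
        beta_out = -out.beta if flipped else out.beta
        instruments.append(
            HarmonizedInstrument(
                snp_id=exp.snp_id,
                beta_exposure=exp.beta,
                se_exposure=exp.se,
                beta_outcome=beta_out,
                se_outcome=out.se,
                exposure_p=exp.pvalue,
                outcome_p=out.pvalue,
                flipped=flipped,
                eaf=exp.eaf,
                n_exposure=exp.n,
                n_outcome=out.n,
            )
        )
    if not instruments:
        raise EmptySetError(
            f"no instrument survived harmonization for {exposure_name} on {outcome_name}"
        )
    return InstrumentSet(
        exposure_name=exposure_name,
        outcome_name=outcome_name,
        population=population,
        instruments=instruments,
        sd_unit=sd_unit,
    )
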