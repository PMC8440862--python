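"""Reading, validating and writing GWAS summary-statistic tables and LD matrices.

Summary statistics are tab-separated text with a header row, one SNP per
row (GWAS-SSF-like).  The default header set is ``rsid, effect_allele,
other_allele, eaf, beta, se, pvalue, n``; real dialects are mapped onto it
with a ``column_map``.  LD matrices are square TSVs whose first column
holds rsid labels and whose remaining columns follow the labelled order.

All numeric round-trips are exact at float64 precision: floats are written
with 17 significant digits.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DataError

__all__ = [
    "SnpAssociation",
    "SummaryTable",
    "LdMatrix",
    "DEFAULT_COLUMNS",
    "read_summary_table",
    "write_summary_table",
    "read_ld_matrix",
    "write_ld_matrix",
]

VALID_BASES = frozenset("ACGT")

#: canonical column order for summary-statistic TSVs
DEFAULT_COLUMNS = (
    "rsid",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
    "n",
)


@dataclass(frozen=True)
class SnpAssociation:
    """One SNP's summary association with one trait.

    Parameters
    ----------
    rsid : str
        Variant identifier (matching between tables is by rsid only).
    effect_allele, other_allele : str
        Single bases in ``{A, C, G, T}``; must differ.
    eaf : float or None
        Effect-allele frequency in (0, 1).  ``None`` is tolerated at read
        time but blocks palindromic-strand inference downstream.
    beta : float
        Additive per-allele effect on the trait, in trait units.
    se : float
        Standard error of ``beta``; strictly positive.
    pvalue : float
        Two-sided association p-value in (0, 1].
    n : int
        Sample size of the association analysis.
    trait_id : str
        Label of the trait / dataset the association refers to.
    """

    rsid: str
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta: float
    se: float
    pvalue: float
    n: int
    trait_id: str = ""

    def validate(self) -> None:
        """Raise :class:`DataError` on any hard-invariant violation."""
        if self.effect_allele not in VALID_BASES:
            raise DataError(
                f"{self.rsid}: effect allele {self.effect_allele!r} is not one of A/C/G/T"
            )
        if self.other_allele not in VALID_BASES:
            raise DataError(
                f"{self.rsid}: other allele {self.other_allele!r} is not one of A/C/G/T"
            )
        if self.effect_allele == self.other_allele:
            raise DataError(f"{self.rsid}: effect and other allele are identical")
        if self.eaf is not None and not (0.0 < self.eaf < 1.0):
            raise DataError(f"{self.rsid}: eaf {self.eaf} outside (0, 1)")
        if not (self.se > 0.0) or not math.isfinite(self.se):
            raise DataError(f"{self.rsid}: se {self.se} must be finite and > 0")
        if not math.isfinite(self.beta):
            raise DataError(f"{self.rsid}: beta {self.beta} is not finite")
        if not (0.0 < self.pvalue <= 1.0):
            raise DataError(f"{self.rsid}: pvalue {self.pvalue} outside (0, 1]")
        if self.n < 1:
            raise DataError(f"{self.rsid}: sample size {self.n} must be >= 1")

    def check_p_consistency(self, factor: float = 100.0) -> bool:
        """Soft check that ``pvalue`` agrees with the normal p implied by beta/se.

        Published tables are not always z-consistent, so a mismatch only
        emits a warning.  Returns ``True`` when consistent within
        ``factor`` (ratio of the two p-values on whichever side is larger).
        """
        implied = 2.0 * stats.norm.sf(abs(self.beta) / self.se)
        if implied <= 0.0:
            return True
        ratio = max(self.pvalue / implied, implied / self.pvalue)
        if ratio > factor:
            warnings.warn(
                f"{self.rsid}: reported p {self.pvalue:.3g} differs from the "
                f"|beta|/se implied p {implied:.3g} by more than {factor:g}x",
                stacklevel=2,
            )
            return False
        return True

    @property
    def maf(self) -> float | None:
        """Minor-allele frequency, ``min(eaf, 1 - eaf)``."""
        return None if self.eaf is None else min(self.eaf, 1.0 - self.eaf)


@dataclass
class SummaryTable:
    """Ordered collection of :class:`SnpAssociation` for one trait.

    rsids are unique; all records carry the table's ``trait_id``.
    """

    records: list[SnpAssociation] = field(default_factory=list)
    trait_id: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.rsid in seen:
                raise DataError(f"duplicate rsid {rec.rsid} in table {self.trait_id!r}")
            seen.add(rec.rsid)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def get(self, rsid: str) -> SnpAssociation | None:
        for rec in self.records:
            if rec.rsid == rsid:
                return rec
        return None

    @property
    def rsids(self) -> list[str]:
        return [rec.rsid for rec in self.records]

    def to_frame(self) -> pd.DataFrame:
        """Summary table as a pandas DataFrame in canonical column order."""
        return pd.DataFrame(
            {
                "rsid": [r.rsid for r in self.records],
                "effect_allele": [r.effect_allele for r in self.records],
                "other_allele": [r.other_allele for r in self.records],
                "eaf": [np.nan if r.eaf is None else r.eaf for r in self.records],
                "beta": [r.beta for r in self.records],
                "se": [r.se for r in self.records],
                "pvalue": [r.pvalue for r in self.records],
                "n": [r.n for r in self.records],
            }
        )

    def subset(self, rsids) -> "SummaryTable":
        """New table with records restricted to ``rsids`` (input order kept)."""
        keep = set(rsids)
        return SummaryTable(
            records=[r for r in self.records if r.rsid in keep],
            trait_id=self.trait_id,
        )


@dataclass
class LdMatrix:
    """Pairwise squared-correlation (r²) matrix over an ordered rsid list."""

    rsids: list[str]
    r2: np.ndarray

    _SYM_TOL = 1e-8

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        k = len(self.rsids)
        if self.r2.shape != (k, k):
            raise DataError(
                f"LD matrix shape {self.r2.shape} does not match {k} rsid labels"
            )
        if len(set(self.rsids)) != k:
            raise DataError("duplicate rsid labels in LD matrix")
        if not np.allclose(self.r2, self.r2.T, atol=self._SYM_TOL, rtol=0.0):
            raise DataError("LD matrix is not symmetric within tolerance 1e-8")
        if not np.allclose(np.diag(self.r2), 1.0, atol=self._SYM_TOL, rtol=0.0):
            raise DataError("LD matrix diagonal must be exactly 1")
        if np.any(self.r2 < 0.0) or np.any(self.r2 > 1.0 + self._SYM_TOL):
            raise DataError("LD r2 entries must lie in [0, 1]")
        # enforce exact symmetry/diagonal after validation
        self.r2 = np.clip((self.r2 + self.r2.T) / 2.0, 0.0, 1.0)
        np.fill_diagonal(self.r2, 1.0)
        self._index = {rsid: i for i, rsid in enumerate(self.rsids)}

    def lookup(self, a: str, b: str) -> float:
        """r² between two labelled variants."""
        try:
            return float(self.r2[self._index[a], self._index[b]])
        except KeyError as exc:
            raise DataError(f"rsid {exc.args[0]} not present in LD matrix") from None

    def covers(self, rsids) -> bool:
        return all(r in self._index for r in rsids)


def _parse_float(value, row: int, column: str, allow_missing: bool = False):
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        if allow_missing:
            return None
        raise DataError(f"row {row}: missing value in column {column!r}")
    try:
        return float(value)
    except (TypeError, ValueError):
        raise DataError(f"row {row}: cannot parse {value!r} in column {column!r}") from None


def read_summary_table(
    path,
    column_map: dict[str, str] | None = None,
    trait_id: str = "",
    p_consistency_factor: float = 100.0,
) -> SummaryTable:
    """Read a TSV of per-SNP summary statistics into a validated table.

    Parameters
    ----------
    path : path-like
        Tab-separated file with a header row.
    column_map : dict, optional
        Mapping from canonical names (see :data:`DEFAULT_COLUMNS`) to the
        file's header names.  Unmapped canonical names are looked up
        verbatim.
    trait_id : str
        Trait label stamped onto every record.
    p_consistency_factor : float
        Tolerated ratio between the reported p and the normal p implied by
        |beta|/se before a warning is emitted.

    Raises
    ------
    ConfigError
        A mapped column is absent from the file.
    DataError
        A row violates a hard invariant; the message cites the 1-based
        data-row number.  All offending rows are reported at once so the
        accept/reject set does not depend on row order.
    """
    column_map = dict(column_map or {})
    df = pd.read_csv(path, sep="\t", dtype={0: str}, float_precision="round_trip")
    resolved = {canon: column_map.get(canon, canon) for canon in DEFAULT_COLUMNS}
    missing = [src for src in resolved.values() if src not in df.columns]
    if missing:
        raise ConfigError(
            f"{path}: missing required column(s) {missing}; present: {list(df.columns)}"
        )

    records: list[SnpAssociation] = []
    problems: list[str] = []
    eaf_missing: list[str] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row = row._asdict()
        try:
            rsid = str(row[resolved["rsid"]]).strip()
            rec = SnpAssociation(
                rsid=rsid,
                effect_allele=str(row[resolved["effect_allele"]]).strip().upper(),
                other_allele=str(row[resolved["other_allele"]]).strip().upper(),
                eaf=_parse_float(row[resolved["eaf"]], i, "eaf", allow_missing=True),
                beta=_parse_float(row[resolved["beta"]], i, "beta"),
                se=_parse_float(row[resolved["se"]], i, "se"),
                pvalue=_parse_float(row[resolved["pvalue"]], i, "pvalue"),
                n=int(_parse_float(row[resolved["n"]], i, "n")),
                trait_id=trait_id,
            )
            rec.validate()
        except DataError as exc:
            problems.append(f"row {i}: {exc}")
            continue
        if rec.eaf is None:
            eaf_missing.append(rec.rsid)
        records.append(rec)

    if problems:
        raise DataError(f"{path}: {len(problems)} invalid row(s): " + "; ".join(problems))
    if eaf_missing:
        warnings.warn(
            f"{path}: eaf missing for {len(eaf_missing)} record(s) "
            f"({', '.join(eaf_missing[:5])}...); palindromic SNPs will not be inferable",
            stacklevel=2,
        )
    table = SummaryTable(records=records, trait_id=trait_id)
    for rec in table:
        rec.check_p_consistency(p_consistency_factor)
    return table


def write_summary_table(table: SummaryTable, path) -> None:
    """Write a summary table as TSV; exact float64 round-trip with
    :func:`read_summary_table` (17 significant digits)."""
    df = table.to_frame()
    df.to_csv(path, sep="\t", index=False, float_format="%.17g", na_rep="")


def read_ld_matrix(path) -> LdMatrix:
    """Read a labelled square r² matrix from TSV.

    The first column holds rsid labels; the remaining column headers must
    repeat the labels in the same order.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    labels = [str(x) for x in df.index]
    if list(df.columns) != labels:
        raise DataError(
            f"{path}: column headers must repeat the row labels in order"
        )
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise DataError(f"{path}: non-numeric entry in LD matrix: {exc}") from None
    return LdMatrix(rsids=labels, r2=values)


def write_ld_matrix(ld: LdMatrix, path) -> None:
    df = pd.DataFrame(ld.r2, index=ld.rsids, columns=ld.rsids)
    df.to_csv(path, sep="\t", float_format="%.17g")


def relabel(record: SnpAssociation, **changes) -> SnpAssociation:
    """Functional update helper (records are frozen)."""
    return replace(record, **changes)
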