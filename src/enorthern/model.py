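"""Domain types and TSV I/O for gene-level EST-profile expression tables.

The central object is a :class:`StudyTable`: an ordered collection of
:class:`GeneProfile` rows, one per gene, each carrying integer
transcripts-per-million (TPM) values for the three compared tissues —
mammary, skin and muscle — plus optional adult/young stage TPMs.  TPM
values are kept as integers because EST-library TPMs are count-derived
(one EST in a library of N reads contributes round(1e6/N)); the reader
rejects non-integer cells rather than silently rounding.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from ._util import round_half_away
from .errors import ParseError, ValidationError

__all__ = [
    "GeneProfile",
    "StudyTable",
    "GENE_ALIASES",
    "read_study_table",
    "write_results_table",
]

#: Maximum admissible TPM value: a gene cannot exceed one million
#: transcripts per million.
TPM_MAX = 10**6

#: Historical gene symbols mapped to their current HGNC names, for joining
#: expression tables against interaction networks that use modern symbols.
GENE_ALIASES: Mapping[str, str] = {
    "ADFP": "PLIN2",
    "ASAHL": "NAAA",
    "LASS2": "CERS2",
}

#: Cell content used for undefined derived values in output tables.
DASH = "—"  # em dash


def _check_tpm(name: str, value: int | None, *, optional: bool = False) -> None:
    if value is None:
        if optional:
            return
        raise ValidationError(f"{name} is required")
    if not isinstance(value, int) or isinstance(value, bool):
        raise ValidationError(f"{name} must be an integer, got {value!r}")
    if not 0 <= value <= TPM_MAX:
        raise ValidationError(f"{name}={value} outside [0, {TPM_MAX}]")


@dataclass(frozen=True)
class GeneProfile:
    """One gene's TPM triplet (mammary, skin, muscle) plus optional stage TPMs.

    Parameters
    ----------
    gene_symbol
        Short uppercase identifier, unique within a table.
    bioprocess
        Functional category label, or ``"unannotated"``.
    tpm_ma, tpm_s, tpm_mu
        Non-negative integer TPM in mammary, skin and muscle tissue.
    tpm_adult, tpm_young
        Optional TPMs from adult- and young-derived tissue, used only for
        the stage-preference comparison.
    """

    gene_symbol: str
    tpm_ma: int
    tpm_s: int
    tpm_mu: int
    bioprocess: str = "unannotated"
    tpm_adult: int | None = None
    tpm_young: int | None = None

    def __post_init__(self) -> None:
        if not self.gene_symbol:
            raise ValidationError("gene_symbol must be non-empty")
        _check_tpm("tpm_ma", self.tpm_ma)
        _check_tpm("tpm_s", self.tpm_s)
        _check_tpm("tpm_mu", self.tpm_mu)
        _check_tpm("tpm_adult", self.tpm_adult, optional=True)
        _check_tpm("tpm_young", self.tpm_young, optional=True)

    @property
    def complete(self) -> bool:
        """Whether the gene has a complete EST profile (all three TPMs > 0)."""
        return self.tpm_ma > 0 and self.tpm_s > 0 and self.tpm_mu > 0


@dataclass
class StudyTable:
    """Ordered, duplicate-free collection of :class:`GeneProfile` rows."""

    profiles: list[GeneProfile]
    source_label: str = ""
    _index: dict[str, GeneProfile] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        index: dict[str, GeneProfile] = {}
        for p in self.profiles:
            if p.gene_symbol in index:
                raise ValidationError(f"duplicate gene {p.gene_symbol!r}")
            index[p.gene_symbol] = p
        self._index = index

    def __len__(self) -> int:
        return len(self.profiles)

    def __iter__(self) -> Iterator[GeneProfile]:
        return iter(self.profiles)

    def __contains__(self, gene_symbol: str) -> bool:
        return gene_symbol in self._index

    def __getitem__(self, gene_symbol: str) -> GeneProfile:
        return self._index[gene_symbol]

    @property
    def gene_symbols(self) -> list[str]:
        return [p.gene_symbol for p in self.profiles]

    def n_complete(self) -> int:
        return sum(p.complete for p in self.profiles)


_DEFAULT_COLUMNS = {
    "gene": "gene",
    "bioprocess": "bioprocess",
    "tpm_ma": "tpm_ma",
    "tpm_s": "tpm_s",
    "tpm_mu": "tpm_mu",
    "tpm_adult": "tpm_adult",
    "tpm_young": "tpm_young",
}


def _parse_tpm(cell: str, column: str, line: int) -> int:
    cell = cell.strip()
    if cell == "" or cell == DASH or cell == "-":
        raise ParseError(f"empty or dashed cell in TPM column {column!r}", line)
    try:
        return int(cell)
    except ValueError:
        raise ParseError(
            f"non-integer value {cell!r} in TPM column {column!r}", line
        ) from None


def read_study_table(
    path: str | Path,
    dialect: str = "tsv",
    columns: Mapping[str, str] | None = None,
) -> StudyTable:
    """Read a tab-separated gene × tissue TPM table.

    The header must name at least the gene column and the three tissue TPM
    columns (``gene``, ``tpm_ma``, ``tpm_s``, ``tpm_mu`` by default;
    ``columns`` remaps logical names to file headers).  Stage TPM columns
    and a bioprocess column are optional.  TPM cells must be plain
    non-negative integers; empty cells and em-dashes are rejected.
    """
    if dialect != "tsv":
        raise ValueError(f"unsupported dialect {dialect!r}")
    path = Path(path)
    colmap = dict(_DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)

    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise ParseError("empty file: missing header row", 1)
        header = set(reader.fieldnames)
        required = [colmap["gene"], colmap["tpm_ma"], colmap["tpm_s"], colmap["tpm_mu"]]
        missing = [c for c in required if c not in header]
        if missing:
            raise ParseError(f"missing required column(s) {missing}", 1)

        profiles: list[GeneProfile] = []
        for row in reader:
            line = reader.line_num
            if None in row or any(v is None for v in row.values()):
                raise ParseError("wrong number of fields", line)
            gene = (row[colmap["gene"]] or "").strip()
            if not gene:
                raise ParseError("empty gene symbol", line)
            kwargs: dict = {
                "gene_symbol": gene,
                "tpm_ma": _parse_tpm(row[colmap["tpm_ma"]], colmap["tpm_ma"], line),
                "tpm_s": _parse_tpm(row[colmap["tpm_s"]], colmap["tpm_s"], line),
                "tpm_mu": _parse_tpm(row[colmap["tpm_mu"]], colmap["tpm_mu"], line),
            }
            if colmap["bioprocess"] in header:
                bp = (row[colmap["bioprocess"]] or "").strip()
                kwargs["bioprocess"] = bp or "unannotated"
            for stage in ("tpm_adult", "tpm_young"):
                col = colmap[stage]
                if col in header:
                    cell = (row[col] or "").strip()
                    if cell:  # absent stage TPMs are legal
                        kwargs[stage] = _parse_tpm(cell, col, line)
            try:
                profiles.append(GeneProfile(**kwargs))
            except ValidationError as exc:
                raise ValidationError(f"line {line}: {exc}") from exc

    return StudyTable(profiles, source_label=str(path))


def _fmt(value: float | None, decimals: int = 3) -> str:
    if value is None:
        return DASH
    return f"{round_half_away(value, decimals):.{decimals}f}"


def write_results_table(results: Iterable, path: str | Path, decimals: int = 3) -> None:
    """Write derived per-gene statistics as a TSV in the study-table layout.

    Columns: gene, tpm_ma, tpm_s, tpm_mu, pct_abundance, ratio_ma_s, e_r,
    status.  Undefined numeric values are rendered as an em-dash; defined
    values with exactly ``decimals`` decimal places.  The TPM columns make
    the output re-readable by :func:`read_study_table`.
    """
    results = list(results)
    if not results:
        raise ValidationError("refusing to write an empty results table")
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["gene", "tpm_ma", "tpm_s", "tpm_mu", "pct_abundance",
             "ratio_ma_s", "e_r", "status"]
        )
        for r in results:
            p = r.profile
            writer.writerow(
                [
                    r.gene_symbol,
                    p.tpm_ma,
                    p.tpm_s,
                    p.tpm_mu,
                    _fmt(r.pct_abundance, decimals),
                    _fmt(r.ratio_ma_s, decimals),
                    _fmt(r.e_r, decimals),
                    r.status.name,
                ]
            )
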