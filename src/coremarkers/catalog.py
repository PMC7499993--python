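"""Machine-readable catalog of the 26 curated responder/non-responder cohorts.

The packaged fixture transcribes the published overview table verbatim: 26
rows covering 2786 cancer cases (breast, lung, glioma, uterine, myeloma and
pediatric leukemia/kidney cohorts) with their therapies, platforms, cohort
sizes, responder/non-responder splits and the number of core marker genes
each cohort yielded. Three rows print an R/NR split that does not sum to N;
the fixture preserves the printed numbers and ``validate_rn_split`` reports
them rather than correcting — the catalog is a citation artifact, and all
summary totals use the N column only.

The one accession appearing twice (TARGET-20) is distinguished by row_id and
therapy text; dataset_id uniqueness is deliberately not an invariant. The
uterine cohort is stored under the printed id "TCGA-UC" (the standard
project code is TCGA-UCEC).
"""

from __future__ import annotations

import csv
from dataclasses import asdict, dataclass
from importlib import resources
from pathlib import Path

from .errors import DataError
from .response import RESPONSE_RULES

__all__ = [
    "CatalogRecord",
    "CatalogSummary",
    "load_catalog",
    "summarize",
    "validate_rn_split",
    "filter_by_core_genes",
    "DEFAULT_MIN_CORE",
]

DEFAULT_MIN_CORE = 7  # suitable cohorts yielded 7-20 core genes
MAX_Q = 30

_COLUMNS = [
    "row_id", "dataset_id", "disease", "therapy", "platform", "platform_type",
    "n_cases", "n_responders", "n_nonresponders", "n_core_genes",
    "response_rule_id",
]

_RNASEQ_PLATFORM = "Illumina HiSeq 2000"


@dataclass(frozen=True)
class CatalogRecord:
    """One catalog row: a cohort and its selection outcome."""

    row_id: int
    dataset_id: str
    disease: str
    therapy: str
    platform: str
    platform_type: str
    n_cases: int
    n_responders: int
    n_nonresponders: int
    n_core_genes: int
    response_rule_id: str

    def __post_init__(self) -> None:
        if self.n_cases < 40:
            raise DataError(
                f"row {self.row_id}: n_cases {self.n_cases} violates the "
                "inclusion criterion of at least 40 expression profiles"
            )
        if self.platform_type not in ("microarray", "rnaseq"):
            raise DataError(
                f"row {self.row_id}: unknown platform_type '{self.platform_type}'"
            )
        is_hiseq = _RNASEQ_PLATFORM in self.platform
        if (self.platform_type == "rnaseq") != is_hiseq:
            raise DataError(
                f"row {self.row_id}: platform_type '{self.platform_type}' "
                f"inconsistent with platform '{self.platform}'"
            )
        if not (0 <= self.n_core_genes <= MAX_Q):
            raise DataError(
                f"row {self.row_id}: n_core_genes {self.n_core_genes} cannot "
                f"exceed Q={MAX_Q}"
            )
        if min(self.n_responders, self.n_nonresponders) < 0:
            raise DataError(f"row {self.row_id}: negative class count")
        if self.response_rule_id not in RESPONSE_RULES:
            raise DataError(
                f"row {self.row_id}: unknown response_rule_id "
                f"'{self.response_rule_id}'"
            )

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class CatalogSummary:
    """Headline totals over a set of catalog records."""

    n_datasets: int
    total_cases: int
    n_rnaseq_datasets: int
    rnaseq_cases: int
    min_cases: int
    max_cases: int
    n_suitable: int

    def to_dict(self) -> dict:
        return asdict(self)


def _default_fixture_path() -> Path:
    return Path(resources.files("coremarkers").joinpath("data/table1_catalog.tsv"))


def load_catalog(path: str | Path | None = None) -> list[CatalogRecord]:
    """Load the packaged catalog fixture (or a file in the same dialect).

    Returns the records in table reading order. Malformed rows, duplicate
    row ids and unknown response rules raise :class:`DataError` naming the
    offending row.
    """
    path = Path(path) if path is not None else _default_fixture_path()
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames != _COLUMNS:
            raise DataError(
                f"{path.name}: unexpected header {reader.fieldnames}; "
                f"expected {_COLUMNS}"
            )
        records: list[CatalogRecord] = []
        seen: set[int] = set()
        for lineno, row in enumerate(reader, start=2):
            if any(v is None for v in row.values()) or None in row:
                raise DataError(f"{path.name}: malformed row at line {lineno}")
            try:
                rec = CatalogRecord(
                    row_id=int(row["row_id"]),
                    dataset_id=row["dataset_id"],
                    disease=row["disease"],
                    therapy=row["therapy"],
                    platform=row["platform"],
                    platform_type=row["platform_type"],
                    n_cases=int(row["n_cases"]),
                    n_responders=int(row["n_responders"]),
                    n_nonresponders=int(row["n_nonresponders"]),
                    n_core_genes=int(row["n_core_genes"]),
                    response_rule_id=row["response_rule_id"],
                )
            except ValueError as exc:
                raise DataError(
                    f"{path.name}: malformed row at line {lineno}: {exc}"
                ) from exc
            if rec.row_id in seen:
                raise DataError(
                    f"{path.name}: duplicate row_id {rec.row_id} at line {lineno}"
                )
            seen.add(rec.row_id)
            records.append(rec)
    if not records:
        raise DataError(f"{path.name}: catalog holds no records")
    return records


def summarize(
    records: list[CatalogRecord], min_core: int = DEFAULT_MIN_CORE
) -> CatalogSummary:
    """Headline totals: dataset/case counts, RNA-seq coverage, suitability.

    A record is counted suitable when it yielded at least ``min_core`` core
    marker genes.
    """
    if not records:
        raise DataError("summarize requires at least one catalog record")
    cases = [r.n_cases for r in records]
    rnaseq = [r for r in records if r.platform_type == "rnaseq"]
    return CatalogSummary(
        n_datasets=len(records),
        total_cases=sum(cases),
        n_rnaseq_datasets=len(rnaseq),
        rnaseq_cases=sum(r.n_cases for r in rnaseq),
        min_cases=min(cases),
        max_cases=max(cases),
        n_suitable=sum(r.n_core_genes >= min_core for r in records),
    )


def validate_rn_split(records: list[CatalogRecord]) -> list[int]:
    """Row ids whose printed R + NR split does not sum to the printed N.

    The fixture transcribes the source table verbatim, inconsistencies
    included; this check surfaces them.
    """
    return [
        r.row_id
        for r in records
        if r.n_responders + r.n_nonresponders != r.n_cases
    ]


def filter_by_core_genes(
    records: list[CatalogRecord], min_core: int = DEFAULT_MIN_CORE
) -> list[CatalogRecord]:
    """Records judged suitable: at least ``min_core`` core marker genes."""
    return [r for r in records if r.n_core_genes >= min_core]
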