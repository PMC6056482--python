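"""Study-level data model and I/O for case-control SNP meta-analysis.

A *study corpus* is an ordered collection of GWAS case-control studies of a
single biallelic SNP (here CLU rs11136000, minor allele T, major allele C).
Each study carries either full genotype counts (TT / TC / CC) for cases and
controls, or — for studies that published only allele frequencies — the
allele counts (T / C).

The on-disk format is a tab-separated table with a fixed header::

    study_id  first_author  year  country  ethnicity  resolution
    case_TT  case_TC  case_CC  case_T  case_C
    ctrl_TT  ctrl_TC  ctrl_CC  ctrl_T  ctrl_C  platform

Cells not applicable to a study's resolution are left blank.  Counts are
exact integers end-to-end.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterator

import pandas as pd

ETHNICITIES = ("Caucasian", "Asian", "African", "American", "Mixed")

CORPUS_COLUMNS = [
    "study_id", "first_author", "year", "country", "ethnicity", "resolution",
    "case_TT", "case_TC", "case_CC", "case_T", "case_C",
    "ctrl_TT", "ctrl_TC", "ctrl_CC", "ctrl_T", "ctrl_C",
    "platform",
]


class CorpusError(ValueError):
    """Schema or validation failure in a study table."""


class ResolutionError(CorpusError):
    """Operation requires genotype resolution but got allele-only data."""


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype (or allele) counts for one arm of one study.

    For genotype-resolution arms ``n_TT``, ``n_TC`` and ``n_CC`` are the
    minor-homozygote, heterozygote and major-homozygote individual counts;
    allele counts are derived (``n_T = 2·TT + TC``).  For allele-only arms
    only ``n_T`` and ``n_C`` are stored and the genotype fields are None.
    """

    n_TT: int | None = None
    n_TC: int | None = None
    n_CC: int | None = None
    n_T: int | None = None
    n_C: int | None = None

    def __post_init__(self) -> None:
        has_geno = self.n_TT is not None
        if has_geno:
            if self.n_TC is None or self.n_CC is None:
                raise CorpusError("partial genotype triple")
            for v in (self.n_TT, self.n_TC, self.n_CC):
                if int(v) != v or v < 0:
                    raise CorpusError(f"negative or non-integer count: {v}")
        else:
            if self.n_T is None or self.n_C is None:
                raise CorpusError("neither genotype triple nor allele pair given")
            for v in (self.n_T, self.n_C):
                if int(v) != v or v < 0:
                    raise CorpusError(f"negative or non-integer count: {v}")

    @property
    def has_genotypes(self) -> bool:
        return self.n_TT is not None

    @property
    def n_individuals(self) -> int:
        if self.has_genotypes:
            return self.n_TT + self.n_TC + self.n_CC
        total = self.n_T + self.n_C
        if total % 2:
            raise CorpusError("odd allele total cannot be halved to individuals")
        return total // 2

    def allele_counts(self) -> tuple[int, int]:
        """Return ``(n_T, n_C)``, deriving from genotypes when present."""
        if self.has_genotypes:
            return 2 * self.n_TT + self.n_TC, 2 * self.n_CC + self.n_TC
        return self.n_T, self.n_C


def derive_allele_counts(g: GenotypeCounts) -> GenotypeCounts:
    """Collapse a genotype triple to its allele-pair representation.

    Raises :class:`ResolutionError` on allele-only input.
    """
    if not g.has_genotypes:
        raise ResolutionError("derive_allele_counts requires genotype resolution")
    n_t, n_c = g.allele_counts()
    return GenotypeCounts(n_T=n_t, n_C=n_c)


@dataclass(frozen=True)
class StudyRecord:
    """One GWAS study: metadata plus case/control genotype (or allele) counts."""

    study_id: str
    first_author: str
    year: int
    country: str
    ethnicity: str
    resolution: str  # "genotype" | "allele_only"
    cases: GenotypeCounts
    controls: GenotypeCounts
    platform: str = ""

    def __post_init__(self) -> None:
        if self.ethnicity not in ETHNICITIES:
            raise CorpusError(
                f"{self.study_id}: unknown ethnicity {self.ethnicity!r}; "
                f"expected one of {ETHNICITIES}"
            )
        if self.resolution not in ("genotype", "allele_only"):
            raise CorpusError(f"{self.study_id}: bad resolution {self.resolution!r}")
        want_geno = self.resolution == "genotype"
        for arm_name, arm in (("cases", self.cases), ("controls", self.controls)):
            if arm.has_genotypes != want_geno:
                raise CorpusError(
                    f"{self.study_id}: {arm_name} counts do not match "
                    f"resolution={self.resolution}"
                )
            if arm.n_individuals <= 0:
                raise CorpusError(f"{self.study_id}: empty {arm_name} arm")

    @property
    def has_genotypes(self) -> bool:
        return self.resolution == "genotype"

    @property
    def n_cases(self) -> int:
        return self.cases.n_individuals

    @property
    def n_controls(self) -> int:
        return self.controls.n_individuals


@dataclass
class StudyCorpus:
    """Ordered, id-unique collection of studies with provenance."""

    studies: list[StudyRecord]
    source: str = "<memory>"
    checksum: str = ""

    def __post_init__(self) -> None:
        ids = [s.study_id for s in self.studies]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise CorpusError(f"duplicate study_id values: {sorted(dupes)}")

    def __iter__(self) -> Iterator[StudyRecord]:
        return iter(self.studies)

    def __len__(self) -> int:
        return len(self.studies)

    def __getitem__(self, study_id: str) -> StudyRecord:
        for s in self.studies:
            if s.study_id == study_id:
                return s
        raise KeyError(study_id)

    def subset(self, study_ids) -> "StudyCorpus":
        wanted = set(study_ids)
        return StudyCorpus(
            [s for s in self.studies if s.study_id in wanted], source=self.source
        )


def _cell(row, col) -> int | None:
    v = row.get(col)
    if v is None or (isinstance(v, float) and pd.isna(v)) or v == "":
        return None
    f = float(v)
    if f != int(f):
        raise CorpusError(f"non-integer count in column {col}: {v!r}")
    return int(f)


def _record_from_row(row: dict, rownum: int) -> StudyRecord:
    sid = row.get("study_id") or f"<row {rownum}>"
    resolution = row["resolution"]
    try:
        if resolution == "genotype":
            cases = GenotypeCounts(
                n_TT=_cell(row, "case_TT"), n_TC=_cell(row, "case_TC"),
                n_CC=_cell(row, "case_CC"))
            controls = GenotypeCounts(
                n_TT=_cell(row, "ctrl_TT"), n_TC=_cell(row, "ctrl_TC"),
                n_CC=_cell(row, "ctrl_CC"))
        else:
            cases = GenotypeCounts(n_T=_cell(row, "case_T"), n_C=_cell(row, "case_C"))
            controls = GenotypeCounts(n_T=_cell(row, "ctrl_T"), n_C=_cell(row, "ctrl_C"))
        return StudyRecord(
            study_id=str(row["study_id"]),
            first_author=str(row["first_author"]),
            year=int(row["year"]),
            country=str(row["country"]),
            ethnicity=str(row["ethnicity"]),
            resolution=str(resolution),
            cases=cases,
            controls=controls,
            platform="" if pd.isna(row.get("platform")) else str(row.get("platform", "")),
        )
    except CorpusError as e:
        raise CorpusError(f"row {rownum} ({sid}): {e}") from e


def read_corpus(path: str | Path) -> StudyCorpus:
    """Read a genotype-count corpus TSV into a validated :class:`StudyCorpus`.

    Every data row becomes exactly one :class:`StudyRecord`; malformed rows
    raise :class:`CorpusError` naming the row number and study.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = path.read_bytes()
    if not raw.strip():
        raise CorpusError(f"{path}: empty input file")
    df = pd.read_csv(path, sep="\t", dtype=object)
    missing = [c for c in CORPUS_COLUMNS if c not in df.columns]
    if missing:
        raise CorpusError(f"{path}: missing required columns {missing}")
    if df.empty:
        raise CorpusError(f"{path}: no study rows")
    records = [
        _record_from_row(row, i + 2)  # +2: header line is 1
        for i, row in enumerate(df.to_dict("records"))
    ]
    return StudyCorpus(records, source=str(path),
                       checksum=hashlib.sha256(raw).hexdigest())


def write_corpus(corpus: StudyCorpus, path: str | Path) -> None:
    """Write a corpus in the canonical TSV dialect (round-trips exactly)."""
    rows = []
    for s in corpus:
        row = {c: "" for c in CORPUS_COLUMNS}
        row.update(study_id=s.study_id, first_author=s.first_author, year=s.year,
                   country=s.country, ethnicity=s.ethnicity,
                   resolution=s.resolution, platform=s.platform)
        if s.has_genotypes:
            row.update(case_TT=s.cases.n_TT, case_TC=s.cases.n_TC,
                       case_CC=s.cases.n_CC,
                       ctrl_TT=s.controls.n_TT, ctrl_TC=s.controls.n_TC,
                       ctrl_CC=s.controls.n_CC)
        else:
            row.update(case_T=s.cases.n_T, case_C=s.cases.n_C,
                       ctrl_T=s.controls.n_T, ctrl_C=s.controls.n_C)
        rows.append(row)
    pd.DataFrame(rows, columns=CORPUS_COLUMNS).to_csv(path, sep="\t", index=False)


def corpus_summary(corpus: StudyCorpus) -> dict:
    """Study count, case/control totals, and per-ethnicity study counts."""
    if len(corpus) == 0:
        raise CorpusError("empty corpus")
    by_eth: dict[str, int] = {}
    for s in corpus:
        by_eth[s.ethnicity] = by_eth.get(s.ethnicity, 0) + 1
    return {
        "n_studies": len(corpus),
        "total_cases": sum(s.n_cases for s in corpus),
        "total_controls": sum(s.n_controls for s in corpus),
        "by_ethnicity": by_eth,
    }


# ---------------------------------------------------------------------------
# Packaged study-metadata table (author, year, country, ethnicity, sample
# sizes, genotyping platform, resolution) for the 50 published rs11136000
# case-control studies.  Per-study genotype counts were published only as a
# journal supplement and are not redistributed here; full-count corpora for
# pipeline runs come from snpmeta.synthetic_data.

def load_table1_metadata() -> pd.DataFrame:
    """Load the packaged 50-study metadata table as a DataFrame."""
    with resources.files("snpmeta.data").joinpath("table1_studies.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return df


def table1_summary() -> dict:
    """Summarize the packaged metadata table (counts sum over all 50 studies)."""
    df = load_table1_metadata()
    return {
        "n_studies": int(len(df)),
        "total_cases": int(df["n_cases"].sum()),
        "total_controls": int(df["n_controls"].sum()),
        "by_ethnicity": df.groupby("ethnicity").size().to_dict(),
        "n_genotype_resolution": int((df["resolution"] == "genotype").sum()),
    }
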