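"""Reading, validating and writing on-disk screen artifacts.

All tabular artifacts are tab-separated UTF-8 text; lines starting with
``#`` are comments.  Identifiers (guides, genes, samples) are
case-sensitive and whitespace-stripped.  Validation collects *every*
problem before raising, since a genome-wide library has >10^5 guides and
a fail-on-first loop is unusable.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ScreenFormatError",
    "CountMatrix",
    "LibraryDesign",
    "SampleSheet",
    "GeneSetCollection",
    "GeneResult",
    "ValidationReport",
    "read_count_table",
    "read_library_map",
    "read_sample_sheet",
    "read_gmt",
    "validate_screen",
    "write_count_table",
    "write_library_map",
    "write_sample_sheet",
    "write_gene_results",
    "read_gene_results",
]

#: column order of the gene-results table (the Supplementary-Table-1 analogue)
GENE_RESULT_COLUMNS = (
    "gene",
    "n_guides",
    "crispr_score",
    "p_value",
    "fdr",
    "rank",
    "hit_class",
)

HIT_CLASSES = (
    "strong_enriched",
    "enriched",
    "depleted_significant",
    "not_significant",
    "filtered",
)


class ScreenFormatError(ValueError):
    """Raised on malformed or inconsistent screen artifacts.

    Carries the full list of problems in :attr:`errors`; the message joins
    them all.
    """

    def __init__(self, errors: Sequence[str]):
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


def _raise_if(errors: list[str]) -> None:
    if errors:
        raise ScreenFormatError(errors)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CountMatrix:
    """Non-negative integer sgRNA x sample abundance table."""

    guide_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    counts: np.ndarray  # shape (n_guides, n_samples), integer dtype

    def __post_init__(self):
        errors: list[str] = []
        counts = np.asarray(self.counts)
        if counts.shape != (len(self.guide_ids), len(self.sample_ids)):
            errors.append(
                f"counts shape {counts.shape} inconsistent with "
                f"{len(self.guide_ids)} guides x {len(self.sample_ids)} samples"
            )
        if len(set(self.guide_ids)) != len(self.guide_ids):
            dup = _duplicates(self.guide_ids)
            errors.append(f"duplicate guide ids: {dup}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            errors.append(f"duplicate sample ids: {_duplicates(self.sample_ids)}")
        if not errors:
            if not np.issubdtype(counts.dtype, np.integer):
                if np.all(counts == np.floor(counts)):
                    counts = counts.astype(np.int64)
                else:
                    errors.append("counts must be integer-valued")
            if not errors and (counts < 0).any():
                bad = np.argwhere(counts < 0)
                msgs = [
                    f"negative count for guide {self.guide_ids[i]!r} "
                    f"sample {self.sample_ids[j]!r}"
                    for i, j in bad[:20]
                ]
                errors.extend(msgs)
        _raise_if(errors)
        object.__setattr__(self, "counts", counts.astype(np.int64))
        object.__setattr__(self, "guide_ids", tuple(self.guide_ids))
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))

    @property
    def n_guides(self) -> int:
        return len(self.guide_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts.copy(), index=list(self.guide_ids), columns=list(self.sample_ids)
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CountMatrix":
        return cls(tuple(map(str, df.index)), tuple(map(str, df.columns)), df.to_numpy())

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return CountMatrix(self.guide_ids, tuple(sample_ids), self.counts[:, idx])


@dataclass(frozen=True)
class LibraryDesign:
    """Mapping of each sgRNA to the single gene it targets."""

    entries: Mapping[str, str]  # guide id -> gene symbol

    def __post_init__(self):
        errors = [
            f"guide {g!r} maps to empty gene symbol"
            for g, sym in self.entries.items()
            if not str(sym).strip()
        ]
        _raise_if(errors)
        object.__setattr__(self, "entries", dict(self.entries))

    @property
    def genes(self) -> set[str]:
        return set(self.entries.values())

    def guides_for(self, gene: str) -> list[str]:
        return [g for g, sym in self.entries.items() if sym == gene]

    def guides_per_gene(self) -> pd.Series:
        return pd.Series(self.entries, name="gene").value_counts().sort_index()


@dataclass(frozen=True)
class SampleSheet:
    """Per-sample experimental annotation.

    ``arm`` is ``control`` or ``treated``; controls carry concentration 0
    and timepoint 0, treated samples a positive concentration (uM) and a
    timepoint index >= 1.
    """

    samples: pd.DataFrame  # index: sample id; columns arm, concentration_uM, timepoint

    def __post_init__(self):
        df = self.samples.copy()
        errors: list[str] = []
        required = {"arm", "concentration_uM", "timepoint"}
        missing = required - set(df.columns)
        if missing:
            _raise_if([f"sample sheet missing columns: {sorted(missing)}"])
        if df.index.duplicated().any():
            errors.append(f"duplicate sample ids: {list(df.index[df.index.duplicated()])}")
        bad_arm = df.index[~df["arm"].isin(["control", "treated"])]
        errors.extend(f"sample {s!r}: arm must be control|treated" for s in bad_arm)
        if not (df["arm"] == "control").any():
            errors.append("sample sheet has no control sample")
        treated = df[df["arm"] == "treated"]
        errors.extend(
            f"treated sample {s!r} must have concentration > 0"
            for s in treated.index[treated["concentration_uM"] <= 0]
        )
        errors.extend(
            f"treated sample {s!r} must have timepoint >= 1"
            for s in treated.index[treated["timepoint"] < 1]
        )
        _raise_if(errors)
        object.__setattr__(self, "samples", df)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples.index)

    @property
    def control_ids(self) -> list[str]:
        return list(self.samples.index[self.samples["arm"] == "control"])

    @property
    def treated_ids(self) -> list[str]:
        return list(self.samples.index[self.samples["arm"] == "treated"])

    def timepoints(self) -> list[int]:
        tp = self.samples.loc[self.samples["arm"] == "treated", "timepoint"]
        return sorted(set(int(t) for t in tp))


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets (GMT-style), with optional per-set descriptions."""

    sets: Mapping[str, frozenset[str]]
    descriptions: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        errors = [f"gene set {name!r} is empty" for name, mem in self.sets.items() if not mem]
        _raise_if(errors)
        object.__setattr__(
            self, "sets", {name: frozenset(mem) for name, mem in self.sets.items()}
        )
        object.__setattr__(self, "descriptions", dict(self.descriptions))

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


@dataclass(frozen=True)
class GeneResult:
    """Gene-level outcome: CRISPR score, KS significance, FDR, rank, class."""

    gene: str
    n_guides: int
    crispr_score: float
    p_value: float | None
    fdr: float | None
    rank: int | None
    hit_class: str

    def __post_init__(self):
        if self.hit_class not in HIT_CLASSES:
            raise ScreenFormatError([f"unknown hit_class {self.hit_class!r}"])


@dataclass(frozen=True)
class ValidationReport:
    """Outcome of cross-checking counts against library and sample sheet."""

    errors: tuple[str, ...]
    guides_per_gene: pd.Series
    low_guide_genes: tuple[str, ...]
    min_guides: int

    @property
    def ok(self) -> bool:
        return not self.errors


def _duplicates(items: Iterable[str]) -> list[str]:
    seen: set[str] = set()
    dup: list[str] = []
    for x in items:
        if x in seen and x not in dup:
            dup.append(x)
        seen.add(x)
    return dup


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)


def read_count_table(path) -> CountMatrix:
    """Read a guide x sample TSV of integer read counts.

    First column holds guide ids, the header row sample ids.
    """
    raw = _read_tsv(path)
    if raw.shape[1] < 2:
        raise ScreenFormatError([f"{path}: count table needs a guide column and >=1 sample"])
    guide_col = raw.columns[0]
    guides = [g.strip() for g in raw[guide_col]]
    samples = [str(c).strip() for c in raw.columns[1:]]
    errors: list[str] = []
    values = np.zeros((len(guides), len(samples)), dtype=np.int64)
    for j, s in enumerate(samples):
        col = raw.iloc[:, j + 1].str.strip()
        numeric = pd.to_numeric(col, errors="coerce")
        bad = numeric.isna() | (numeric != np.floor(numeric.fillna(0)))
        for i in np.flatnonzero(bad.to_numpy()):
            errors.append(
                f"non-integer count {col.iloc[i]!r} for guide {guides[i]!r} sample {s!r}"
            )
        neg = numeric < 0
        for i in np.flatnonzero(neg.to_numpy()):
            errors.append(f"negative count for guide {guides[i]!r} sample {s!r}")
        if not (bad.any() or neg.any()):
            values[:, j] = numeric.astype(np.int64)
    errors.extend(f"duplicate guide id {g!r}" for g in _duplicates(guides))
    _raise_if(errors)
    return CountMatrix(tuple(guides), tuple(samples), values)


def read_library_map(path) -> LibraryDesign:
    """Read a two-column guide-id -> gene-symbol TSV."""
    raw = _read_tsv(path)
    if raw.shape[1] < 2:
        raise ScreenFormatError([f"{path}: library map needs guide and gene columns"])
    errors: list[str] = []
    entries: dict[str, str] = {}
    for guide, gene in zip(raw.iloc[:, 0], raw.iloc[:, 1]):
        guide, gene = guide.strip(), gene.strip()
        if not gene:
            errors.append(f"guide {guide!r} has empty gene symbol")
            continue
        if guide in entries and entries[guide] != gene:
            errors.append(
                f"guide {guide!r} mapped to both {entries[guide]!r} and {gene!r}"
            )
            continue
        entries[guide] = gene
    _raise_if(errors)
    return LibraryDesign(entries)


def read_sample_sheet(path) -> SampleSheet:
    """Read the sample sheet (sample_id, arm, concentration_uM, timepoint)."""
    raw = _read_tsv(path)
    errors: list[str] = []
    required = ["sample_id", "arm", "concentration_uM", "timepoint"]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise ScreenFormatError([f"{path}: sample sheet missing columns {missing}"])
    df = raw[required].copy()
    df["sample_id"] = df["sample_id"].str.strip()
    df["arm"] = df["arm"].str.strip()
    for col in ("concentration_uM", "timepoint"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
        errors.extend(
            f"sample {s!r}: non-numeric {col}"
            for s in df["sample_id"][df[col].isna()]
        )
    _raise_if(errors)
    df["timepoint"] = df["timepoint"].astype(int)
    return SampleSheet(df.set_index("sample_id"))


def read_gmt(path) -> GeneSetCollection:
    """Read gene sets in GMT format (name, description, members; tab-separated)."""
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    errors: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                errors.append(f"line {lineno}: GMT line needs name, description, >=1 member")
                continue
            name = parts[0].strip()
            members = frozenset(p.strip() for p in parts[2:] if p.strip())
            if not members:
                errors.append(f"line {lineno}: gene set {name!r} has no members")
                continue
            if name in sets:
                errors.append(f"line {lineno}: duplicate set name {name!r}")
                continue
            sets[name] = members
            descriptions[name] = parts[1].strip()
    _raise_if(errors)
    return GeneSetCollection(sets, descriptions)


# ---------------------------------------------------------------------------
# cross validation
# ---------------------------------------------------------------------------


def validate_screen(
    counts: CountMatrix,
    lib: LibraryDesign,
    sheet: SampleSheet,
    min_guides: int = 3,
) -> ValidationReport:
    """Cross-check counts against library design and sample sheet.

    Pure function: inputs are never mutated.  All cross-reference failures
    are reported together; the guides-per-gene distribution and genes below
    ``min_guides`` are always reported.
    """
    errors: list[str] = []
    missing_guides = [g for g in counts.guide_ids if g not in lib.entries]
    if missing_guides:
        errors.append(
            f"{len(missing_guides)} guide(s) in counts absent from library: "
            + ", ".join(missing_guides[:20])
        )
    sheet_ids = set(sheet.sample_ids)
    missing_samples = [s for s in counts.sample_ids if s not in sheet_ids]
    errors.extend(f"sample {s!r} in counts absent from sample sheet" for s in missing_samples)
    present = [g for g in counts.guide_ids if g in lib.entries]
    gpg = pd.Series({g: lib.entries[g] for g in present}, name="gene").value_counts().sort_index()
    low = tuple(gpg.index[gpg < min_guides])
    return ValidationReport(tuple(errors), gpg, low, min_guides)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def _write_text(path, text: str) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(text)


def write_count_table(counts: CountMatrix, path) -> None:
    buf = _stdio.StringIO()
    buf.write("guide_id\t" + "\t".join(counts.sample_ids) + "\n")
    for g, row in zip(counts.guide_ids, counts.counts):
        buf.write(g + "\t" + "\t".join(str(int(v)) for v in row) + "\n")
    _write_text(path, buf.getvalue())


def write_library_map(lib: LibraryDesign, path) -> None:
    lines = ["guide_id\tgene"]
    lines += [f"{g}\t{sym}" for g, sym in lib.entries.items()]
    _write_text(path, "\n".join(lines) + "\n")


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    buf = _stdio.StringIO()
    buf.write("sample_id\tarm\tconcentration_uM\ttimepoint\n")
    for sid, row in sheet.samples.iterrows():
        buf.write(f"{sid}\t{row['arm']}\t{row['concentration_uM']:g}\t{int(row['timepoint'])}\n")
    _write_text(path, buf.getvalue())


def _fmt_float(x) -> str:
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return "NA"
    return format(float(x), ".8g")


def write_gene_results(results: Sequence[GeneResult] | pd.DataFrame, path) -> None:
    """Write gene results as TSV in the fixed documented column order.

    Rows are ordered by rank (ranked genes first), then gene symbol; floats
    carry 8 significant digits so a read-back reproduces them at the
    documented >=6-digit precision.
    """
    if isinstance(results, pd.DataFrame):
        rows = [
            GeneResult(
                gene=str(r.gene),
                n_guides=int(r.n_guides),
                crispr_score=float(r.crispr_score),
                p_value=None if pd.isna(r.p_value) else float(r.p_value),
                fdr=None if pd.isna(r.fdr) else float(r.fdr),
                rank=None if pd.isna(r.rank) else int(r.rank),
                hit_class=str(r.hit_class),
            )
            for r in results.itertuples()
        ]
    else:
        rows = list(results)
    if not rows:
        raise ScreenFormatError(["no gene results to write"])
    rows.sort(key=lambda r: (r.rank is None, r.rank if r.rank is not None else 0, r.gene))
    buf = _stdio.StringIO()
    buf.write("\t".join(GENE_RESULT_COLUMNS) + "\n")
    for r in rows:
        buf.write(
            "\t".join(
                [
                    r.gene,
                    str(r.n_guides),
                    _fmt_float(r.crispr_score),
                    _fmt_float(r.p_value),
                    _fmt_float(r.fdr),
                    "NA" if r.rank is None else str(r.rank),
                    r.hit_class,
                ]
            )
            + "\n"
        )
    _write_text(path, buf.getvalue())


def read_gene_results(path) -> pd.DataFrame:
    """Read back a gene-results TSV written by :func:`write_gene_results`."""
    df = pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])
    missing = set(GENE_RESULT_COLUMNS) - set(df.columns)
    if missing:
        raise ScreenFormatError([f"{path}: gene results missing columns {sorted(missing)}"])
    return df
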