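"""File formats and run configuration.

All genomic coordinates are 0-based half-open (BED convention) at every
interface; 1-based numbering exists only for primary positions inside an
element.  TSV outputs use "." for missing values.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .element_space import (
    SCHEMAS,
    HIERARCHIES,
    ElementSchema,
    VacancyHierarchy,
)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Multi-record FASTA as an id -> sequence mapping."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(path: str | Path, records: Mapping[str, str]) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()),
        str(path),
        "fasta",
    )


BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed(path: str | Path) -> pd.DataFrame:
    """3+-column BED; extra columns mapped to name/score/strand."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    except Exception as err:
        raise ValueError(f"malformed BED file {path}: {err}") from err
    if df.shape[1] < 3:
        raise ValueError(f"BED file {path} has fewer than 3 columns")
    df = df.iloc[:, :6]
    df.columns = BED_COLUMNS[: df.shape[1]]
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df


def write_bed(path: str | Path, df: pd.DataFrame) -> None:
    cols = [c for c in BED_COLUMNS if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def occurrences_to_bed6(occ: pd.DataFrame) -> pd.DataFrame:
    """Element occurrences as 6-column BED: name = element id, score = k,
    strand fixed to '+' (scanning is sense-strand only)."""
    out = occ.rename(columns={"element_id": "name", "k": "score"}).copy()
    out["strand"] = "+"
    return out[BED_COLUMNS]


def bed6_to_occurrences(df: pd.DataFrame) -> pd.DataFrame:
    out = df.rename(columns={"name": "element_id", "score": "k"}).copy()
    out["k"] = out["k"].astype(int)
    return out[["chrom", "start", "end", "element_id", "k"]]


def write_tsv(path: str | Path, df: pd.DataFrame, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, na_rep=".")


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["."])


@dataclasses.dataclass
class RunConfig:
    """Validated pipeline configuration (persisted next to outputs)."""

    schema: str = "ERE13"
    k_max: int = 5
    hierarchy: tuple[int, ...] | None = None
    grouping: str | tuple[int, ...] = "auto"
    p_threshold: float = 0.001
    genome: str | None = None
    peaks: str | None = None
    outdir: str = "."
    seed: int = 0

    def resolved_schema(self) -> ElementSchema:
        if self.schema not in SCHEMAS:
            raise ValueError(
                f"unknown schema {self.schema!r}; choose from {sorted(SCHEMAS)}"
            )
        return SCHEMAS[self.schema]

    def resolved_hierarchy(self) -> VacancyHierarchy:
        if self.hierarchy is not None:
            h = VacancyHierarchy(tuple(self.hierarchy))
        else:
            h = HIERARCHIES[self.schema]
        h.validate(self.resolved_schema())
        return h

    def validate(self) -> "RunConfig":
        schema = self.resolved_schema()
        if not 0 <= self.k_max <= schema.n:
            raise ValueError(f"k_max out of range for {self.schema}: {self.k_max}")
        if not 0 < self.p_threshold < 0.5:
            raise ValueError("p_threshold must be in (0, 0.5)")
        self.resolved_hierarchy()
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys in {path}: {sorted(unknown)}")
        if "hierarchy" in raw and raw["hierarchy"] is not None:
            raw["hierarchy"] = tuple(raw["hierarchy"])
        return cls(**raw).validate()

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        if data["hierarchy"] is not None:
            data["hierarchy"] = list(data["hierarchy"])
        if isinstance(data["grouping"], tuple):
            data["grouping"] = list(data["grouping"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
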