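"""Core data containers and TSV readers/writers.

The pipeline works on three tables:

* ``BandMatrix`` — the DGGE fingerprint: a samples x bands nonnegative
  intensity matrix plus a per-band kingdom label (bacteria | fungi).  Bands
  act as operational taxonomic proxies.
* ``SampleTable`` — per-sample treatment factors: phosphate source (with its
  %P2O5 solubility), inoculum addition, replicate.
* ``PhenotypeTable`` — plant responses: total dry matter (g/pot), mycorrhizal
  colonization index (% of root cortex), optional leaf N/P/K.

All on-disk formats are TSV with a header row; samples are rows and bands are
columns in the band matrix, with kingdom labels in a separate two-column file.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "BandMatrix",
    "SampleTable",
    "PhenotypeTable",
    "read_band_matrix",
    "write_band_matrix",
    "read_tables",
    "write_tables",
    "ValidationError",
]

KINGDOMS = ("bacteria", "fungi")
#: canonical source -> %P2O5 mapping of the emulated study
SOURCE_P2O5 = {"Control": 0.0, "CA": 2.93, "BA": 14.0, "SS": 18.0}


class ValidationError(ValueError):
    """An input table violates a structural invariant."""


@dataclass
class BandMatrix:
    """Samples x bands intensity table with per-band kingdom labels."""

    intensities: pd.DataFrame  # index: sample ids, columns: band ids
    kingdom: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.intensities
        if df.index.duplicated().any():
            raise ValidationError("duplicate sample ids in band matrix")
        if df.columns.duplicated().any():
            raise ValidationError("duplicate band ids in band matrix")
        values = df.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValidationError("band intensities must be finite")
        if (values < 0).any():
            raise ValidationError("band intensities must be nonnegative")
        missing = [b for b in df.columns if b not in self.kingdom]
        if missing:
            raise ValidationError(f"bands lacking a kingdom label: {missing}")
        bad = {b: k for b, k in self.kingdom.items() if k not in KINGDOMS}
        if bad:
            raise ValidationError(f"unknown kingdom labels: {bad}")

    # -- convenience accessors -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.intensities.index)

    @property
    def band_ids(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_bands(self) -> int:
        return self.intensities.shape[1]

    def values(self) -> np.ndarray:
        return self.intensities.to_numpy(dtype=float)

    def presence(self) -> pd.DataFrame:
        """Boolean presence/absence table (intensity > 0)."""
        return self.intensities > 0

    def kingdom_of(self, band_id: str) -> str:
        return self.kingdom[band_id]

    def subset_samples(self, sample_ids) -> "BandMatrix":
        sub = self.intensities.loc[list(sample_ids)]
        labels = {b: self.kingdom[b] for b in sub.columns}
        return BandMatrix(sub, labels)

    def subset_bands(self, band_ids) -> "BandMatrix":
        sub = self.intensities[list(band_ids)]
        labels = {b: self.kingdom[b] for b in sub.columns}
        return BandMatrix(sub, labels)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BandMatrix):
            return NotImplemented
        return self.intensities.equals(other.intensities) and self.kingdom == {
            b: other.kingdom.get(b) for b in self.kingdom
        }


@dataclass
class SampleTable:
    """Per-sample treatment factors.

    Columns: sample_id (index), source, p2o5_percent, inoculum (bool),
    replicate (int).
    """

    table: pd.DataFrame

    REQUIRED = ("source", "p2o5_percent", "inoculum", "replicate")

    def __post_init__(self) -> None:
        df = self.table
        for col in self.REQUIRED:
            if col not in df.columns:
                raise ValidationError(f"sample table lacks column {col!r}")
        if df.index.duplicated().any():
            raise ValidationError("duplicate sample ids in sample table")
        unknown = set(df["source"]) - set(SOURCE_P2O5)
        if unknown:
            raise ValidationError(f"unknown phosphate sources: {sorted(unknown)}")
        for src, grp in df.groupby("source"):
            expected = SOURCE_P2O5[str(src)]
            if not np.allclose(grp["p2o5_percent"], expected):
                raise ValidationError(
                    f"source {src!r} must have p2o5_percent {expected}, "
                    f"got {sorted(set(grp['p2o5_percent']))}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SampleTable):
            return NotImplemented
        return self.table.equals(other.table)


@dataclass
class PhenotypeTable:
    """Per-sample plant responses.

    Colonization is structurally zero without inoculum: mycorrhizal
    colonization cannot occur in uninoculated pots, so a nonzero value there
    is rejected as a transcription error.
    """

    table: pd.DataFrame
    samples: SampleTable | None = None

    def __post_init__(self) -> None:
        df = self.table
        for col in ("total_dry_matter", "colonization_index"):
            if col not in df.columns:
                raise ValidationError(f"phenotype table lacks column {col!r}")
        if df.index.duplicated().any():
            raise ValidationError("duplicate sample ids in phenotype table")
        if (df["total_dry_matter"] <= 0).any():
            raise ValidationError("total dry matter must be positive")
        col = df["colonization_index"]
        if ((col < 0) | (col > 100)).any():
            raise ValidationError("colonization index must lie in [0, 100]")
        if self.samples is not None:
            st = self.samples.table
            unknown = set(df.index) - set(st.index)
            if unknown:
                raise ValidationError(
                    f"phenotype samples missing from metadata: {sorted(unknown)}"
                )
            merged = df.join(st, how="left")
            bad = merged[(~merged["inoculum"].astype(bool)) & (merged["colonization_index"] > 0)]
            if len(bad):
                raise ValidationError(
                    "nonzero colonization without inoculum for samples "
                    f"{list(bad.index)}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PhenotypeTable):
            return NotImplemented
        return self.table.equals(other.table)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_band_matrix(path: str | Path, kingdom_path: str | Path) -> BandMatrix:
    """Read a samples x bands TSV plus a two-column band->kingdom TSV."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValidationError(f"non-numeric band intensity: {exc}") from exc
    labels = pd.read_csv(kingdom_path, sep="\t", index_col=0)
    if labels.shape[1] != 1:
        raise ValidationError("kingdom file must have exactly two columns")
    kingdom = labels.iloc[:, 0].astype(str).to_dict()
    return BandMatrix(df, {str(k): v for k, v in kingdom.items()})


def write_band_matrix(matrix: BandMatrix, path: str | Path, kingdom_path: str | Path) -> None:
    matrix.intensities.to_csv(path, sep="\t", index_label="sample_id")
    pd.Series(matrix.kingdom, name="kingdom").rename_axis("band_id").to_csv(
        kingdom_path, sep="\t"
    )


def read_tables(metadata_path: str | Path, phenotype_path: str | Path) -> tuple[SampleTable, PhenotypeTable]:
    """Read and cross-validate the sample metadata and phenotype TSVs."""
    meta = pd.read_csv(metadata_path, sep="\t", index_col=0)
    meta["inoculum"] = meta["inoculum"].map(_parse_bool)
    meta["replicate"] = meta["replicate"].astype(int)
    samples = SampleTable(meta)
    pheno = pd.read_csv(phenotype_path, sep="\t", index_col=0)
    return samples, PhenotypeTable(pheno, samples)


def write_tables(samples: SampleTable, phenotypes: PhenotypeTable, metadata_path: str | Path, phenotype_path: str | Path) -> None:
    samples.table.to_csv(metadata_path, sep="\t", index_label="sample_id")
    phenotypes.table.to_csv(phenotype_path, sep="\t", index_label="sample_id")


def _parse_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    text = str(value).strip().lower()
    if text in ("true", "1", "yes", "+"):
        return True
    if text in ("false", "0", "no", "-"):
        return False
    raise ValidationError(f"cannot parse boolean value {value!r}")
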