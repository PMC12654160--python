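"""Domain tables, delimited-text I/O and dataset validation.

All tables are thin wrappers around :class:`pandas.DataFrame` with the
validation rules of the study design attached.  The canonical on-disk
format is tab-separated text with a header row; feature tables are
features (rows) x samples (columns) with ``feature_id``, ``domain`` and
``taxonomy`` columns, the per-sample tables are samples (rows) x
variables (columns) indexed by ``sample_id``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .reference import TREATMENTS

DOMAINS = ("bacteria", "fungi", "archaea")

ENZYME_COLUMNS = ("BG", "CBH", "NAG", "LAP", "ALP")
P_FRACTION_COLUMNS = ("CaCl2_P", "Citrate_P", "Enzyme_P", "HCl_P")
SOIL_CHEMISTRY_COLUMNS = (
    "pH", "SOM", "TN", "TP", "AK", "AP", "AN", "WEOC", "NO3N",
    "MBC", "MBN", "MBP", "yield",
)


class ValidationError(ValueError):
    """Fatal problem in an input table."""


@dataclass(frozen=True)
class Finding:
    severity: str  # "fatal" | "advisory"
    message: str


@dataclass
class ValidationReport:
    findings: list[Finding] = field(default_factory=list)

    def add(self, severity: str, message: str) -> None:
        self.findings.append(Finding(severity, message))

    @property
    def fatal(self) -> list[Finding]:
        return [f for f in self.findings if f.severity == "fatal"]

    @property
    def advisory(self) -> list[Finding]:
        return [f for f in self.findings if f.severity == "advisory"]

    @property
    def ok(self) -> bool:
        return not self.fatal

    def raise_on_fatal(self) -> None:
        if self.fatal:
            msgs = "; ".join(f.message for f in self.fatal)
            raise ValidationError(f"dataset validation failed: {msgs}")


@dataclass
class SampleMetadata:
    """Sample identifiers with treatment and replicate labels."""

    data: pd.DataFrame  # columns: treatment, replicate; index: sample_id

    def __post_init__(self) -> None:
        df = self.data
        df.index.name = "sample_id"
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dupes}")
        bad = set(df["treatment"]) - set(TREATMENTS)
        if bad:
            raise ValidationError(f"unknown treatments: {sorted(bad)}")
        if (df["replicate"] < 1).any():
            raise ValidationError("replicate numbers must be positive")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def treatments(self) -> pd.Series:
        return self.data["treatment"]

    def samples_for(self, treatment: str) -> list[str]:
        return list(self.data.index[self.data["treatment"] == treatment])

    def is_balanced(self) -> bool:
        counts = self.data.groupby("treatment").size()
        return counts.nunique() == 1

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, str, int]]) -> "SampleMetadata":
        df = pd.DataFrame(records, columns=["sample_id", "treatment", "replicate"])
        return cls(df.set_index("sample_id"))


@dataclass
class FeatureTable:
    """Taxon counts (features x samples) with domain and taxonomy labels."""

    counts: pd.DataFrame            # int counts, index feature_id, columns sample_id
    domain: pd.Series               # per feature: bacteria|fungi|archaea
    taxonomy: pd.Series             # per feature: "k__...;p__...;..."

    def __post_init__(self) -> None:
        if self.counts.shape[0] < 1 or self.counts.shape[1] < 2:
            raise ValidationError("feature table needs >= 1 feature and >= 2 samples")
        self.counts.index.name = "feature_id"
        self.counts.columns.name = None
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            r, c = np.argwhere(vals < 0)[0]
            raise ValidationError(
                f"negative count at feature {self.counts.index[r]!r}, "
                f"sample {self.counts.columns[c]!r}"
            )
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                r, c = np.argwhere(~np.isclose(vals, np.round(vals)))[0]
                raise ValidationError(
                    f"non-integer count at feature {self.counts.index[r]!r}, "
                    f"sample {self.counts.columns[c]!r}"
                )
            self.counts = self.counts.astype(np.int64)
        bad = set(self.domain) - set(DOMAINS)
        if bad:
            raise ValidationError(f"unknown domains: {sorted(bad)}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def phylum(self) -> pd.Series:
        """Phylum extracted from the 'p__' token of each taxonomy string."""
        def _extract(tax: str) -> str:
            m = re.search(r"p__([^;]*)", tax)
            return m.group(1) if m and m.group(1) else "unclassified"
        return self.taxonomy.map(_extract)

    def subset_samples(self, sample_ids: Iterable[str]) -> "FeatureTable":
        ids = list(sample_ids)
        return FeatureTable(self.counts[ids].copy(), self.domain.copy(),
                            self.taxonomy.copy())


def _check_sample_table(df: pd.DataFrame, columns: Iterable[str], name: str,
                        require_all: bool = False) -> None:
    missing = [c for c in columns if c not in df.columns]
    if require_all and missing:
        raise ValidationError(f"{name} missing columns: {missing}")


@dataclass
class SoilChemistryTable:
    """Per-sample soil chemistry (pH, SOM, TN, TP, AK/AP/AN/..., yield)."""

    data: pd.DataFrame  # index sample_id

    def __post_init__(self) -> None:
        df = self.data
        df.index.name = "sample_id"
        conc = [c for c in df.columns if c not in ("pH",)]
        arr = df[conc].to_numpy(dtype=float)
        if np.nanmin(arr, initial=0.0) < 0:
            raise ValidationError("negative concentration in soil chemistry table")
        if "pH" in df.columns:
            ph = df["pH"].to_numpy(dtype=float)
            if ((ph <= 0) | (ph >= 14)).any():
                raise ValidationError("pH out of (0, 14)")


@dataclass
class PFractionTable:
    """Bioavailable P fractions per sample (CaCl2-P, Citrate-P, Enzyme-P, HCl-P)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.data.index.name = "sample_id"
        _check_sample_table(self.data, P_FRACTION_COLUMNS, "P fraction table",
                            require_all=True)
        if (self.data[list(P_FRACTION_COLUMNS)].to_numpy(dtype=float) < 0).any():
            raise ValidationError("negative P fraction value")


@dataclass
class EnzymeActivityTable:
    """Per-sample activities of BG, CBH, NAG, LAP, ALP (nmol h-1 g-1)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.data.index.name = "sample_id"
        _check_sample_table(self.data, ENZYME_COLUMNS, "enzyme table",
                            require_all=True)
        if (self.data[list(ENZYME_COLUMNS)].to_numpy(dtype=float) < 0).any():
            raise ValidationError("negative enzyme activity")


# ---------------------------------------------------------------------------
# Delimited-text I/O

def read_metadata(path: str | Path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    df["replicate"] = df["replicate"].astype(int)
    return SampleMetadata(df.set_index("sample_id"))


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    meta.data.to_csv(path, sep="\t", index_label="sample_id")


def read_feature_table(path: str | Path, metadata: SampleMetadata) -> FeatureTable:
    """Read a features x samples count table, reordering to metadata order.

    The first column is the feature id; ``domain`` and ``taxonomy`` columns
    are carried alongside the sample columns.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    domain = df.pop("domain") if "domain" in df.columns else pd.Series(
        "bacteria", index=df.index)
    taxonomy = df.pop("taxonomy") if "taxonomy" in df.columns else pd.Series(
        "", index=df.index)
    missing = [s for s in metadata.sample_ids if s not in df.columns]
    if missing:
        raise ValidationError(f"feature table missing sample columns: {missing}")
    extra = [c for c in df.columns if c not in metadata.sample_ids]
    if extra:
        raise ValidationError(f"feature table has samples absent from metadata: {extra}")
    counts = df[metadata.sample_ids]
    arr = counts.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise ValidationError("non-numeric counts in feature table")
    return FeatureTable(counts, domain, taxonomy)


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    out = table.counts.copy()
    out.insert(0, "taxonomy", table.taxonomy)
    out.insert(0, "domain", table.domain)
    out.to_csv(path, sep="\t", index_label="feature_id")


def _read_sample_table(path: str | Path, cls, metadata: SampleMetadata | None):
    df = pd.read_csv(path, sep="\t", index_col=0)
    if metadata is not None:
        missing = [s for s in metadata.sample_ids if s not in df.index]
        if missing:
            raise ValidationError(f"table at {path} missing samples: {missing}")
        df = df.loc[metadata.sample_ids]
    return cls(df)


def read_soil_chemistry(path, metadata=None) -> SoilChemistryTable:
    return _read_sample_table(path, SoilChemistryTable, metadata)


def read_p_fractions(path, metadata=None) -> PFractionTable:
    return _read_sample_table(path, PFractionTable, metadata)


def read_enzyme_activities(path, metadata=None) -> EnzymeActivityTable:
    return _read_sample_table(path, EnzymeActivityTable, metadata)


def write_sample_table(table, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# Dataset validation

def validate_dataset(metadata: SampleMetadata, **tables) -> ValidationReport:
    """Cross-check all tables against the sample metadata.

    Missing samples and missing numeric cells are fatal; an unbalanced
    replicate design is advisory only.
    """
    report = ValidationReport()
    counts = metadata.data.groupby("treatment").size()
    if counts.nunique() > 1:
        report.add("advisory",
                   f"unbalanced design: replicate counts {dict(counts)}")
    wanted = set(metadata.sample_ids)
    for name, table in tables.items():
        if table is None:
            continue
        if isinstance(table, FeatureTable):
            have = set(table.sample_ids)
        else:
            have = set(table.data.index)
        missing = sorted(wanted - have)
        if missing:
            report.add("fatal", f"{name} missing samples: {missing}")
        extra = sorted(have - wanted)
        if extra:
            report.add("advisory", f"{name} has extra samples: {extra}")
        if not isinstance(table, FeatureTable):
            n_missing = int(table.data.isna().sum().sum())
            if n_missing:
                report.add("fatal", f"{name} has {n_missing} missing cells")
    return report


@dataclass
class StudyDataset:
    """A full study: metadata plus every measurement table."""

    metadata: SampleMetadata
    features: dict[str, FeatureTable]          # keyed by domain
    soil_chemistry: SoilChemistryTable
    p_fractions: PFractionTable
    enzymes: EnzymeActivityTable

    def validate(self) -> ValidationReport:
        tables = {f"features_{d}": t for d, t in self.features.items()}
        return validate_dataset(self.metadata, soil_chemistry=self.soil_chemistry,
                                p_fractions=self.p_fractions,
                                enzymes=self.enzymes, **tables)

    def pooled_features(self) -> FeatureTable:
        """Concatenate the per-domain tables into one features x samples table."""
        counts = pd.concat([t.counts for t in self.features.values()])
        domain = pd.concat([t.domain for t in self.features.values()])
        taxonomy = pd.concat([t.taxonomy for t in self.features.values()])
        return FeatureTable(counts, domain, taxonomy)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_metadata(self.metadata, outdir / "metadata.tsv")
        for dom, tab in self.features.items():
            write_feature_table(tab, outdir / f"features_{dom}.tsv")
        write_sample_table(self.soil_chemistry, outdir / "soil_chemistry.tsv")
        write_sample_table(self.p_fractions, outdir / "p_fractions.tsv")
        write_sample_table(self.enzymes, outdir / "enzymes.tsv")

    @classmethod
    def read(cls, indir: str | Path) -> "StudyDataset":
        indir = Path(indir)
        meta = read_metadata(indir / "metadata.tsv")
        features = {}
        for dom in DOMAINS:
            p = indir / f"features_{dom}.tsv"
            if p.exists():
                features[dom] = read_feature_table(p, meta)
        return cls(
            metadata=meta,
            features=features,
            soil_chemistry=read_soil_chemistry(indir / "soil_chemistry.tsv", meta),
            p_fractions=read_p_fractions(indir / "p_fractions.tsv", meta),
            enzymes=read_enzyme_activities(indir / "enzymes.tsv", meta),
        )
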