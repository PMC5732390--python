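"""File formats and run configuration.

Formats are deliberately plain: a dosage table (first column sample id,
header row of SNP ids, tab- or comma-delimited, missing coded "NA" —
what a PLINK ``.raw`` export looks like after pruning its bookkeeping
columns), biallelic VCF (dosage = ALT-allele count from GT), a weight
file (TSV: snp_id, risk_allele, weight), per-sample value tables
(TSV: sample_id, value) for phenotypes and exposures, YAML run configs
and TSV/JSON results.  SNPs are identified by id only; there is no
positional or strand logic.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import (
    CODINGS,
    GenotypeMatrix,
    GenotypeValidationError,
    WeightVector,
)

FAMILIES = ("gaussian", "binomial")
WEIGHTING_METHODS = ("external", "marginal-internal", "interaction-training")


class ConfigError(ValueError):
    """Raised for invalid run configurations (checked before any compute)."""


class WeightFileError(ValueError):
    """Raised for malformed weight files."""


# ---------------------------------------------------------------------------
# genotypes


def read_genotypes(path, format: str = "dosage-table") -> GenotypeMatrix:
    """Read a genotype dosage matrix from a dosage table or a VCF.

    Missing entries are flagged in ``GenotypeMatrix.missing``, never
    imputed.  Dosage values outside {0, 1, 2} raise
    :class:`~grsxe.core.GenotypeValidationError`.
    """
    if format == "dosage-table":
        return _read_dosage_table(path)
    if format == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_dosage_table(path) -> GenotypeMatrix:
    try:
        df = pd.read_csv(
            path, sep=None, engine="python", index_col=0,
            na_values=["NA"], keep_default_na=False,
        )
    except pd.errors.ParserError as exc:
        raise GenotypeValidationError(f"malformed dosage table {path}: {exc}") from exc
    if df.shape[1] == 0:
        raise GenotypeValidationError(f"{path}: no SNP columns found")
    values = df.to_numpy(dtype=float)
    missing = np.isnan(values)
    observed = values[~missing]
    bad = ~np.isin(observed, (0.0, 1.0, 2.0))
    if bad.any():
        rows, cols = np.where(~missing)
        flat_bad = np.where(bad)[0][0]
        r, c = rows[flat_bad], cols[flat_bad]
        raise GenotypeValidationError(
            f"{path}: dosage {values[r, c]!r} outside {{0,1,2}} "
            f"(sample {df.index[r]!r}, SNP {df.columns[c]!r})"
        )
    dosages = np.where(missing, 0, values).astype(np.int8)
    return GenotypeMatrix(
        dosages=dosages,
        sample_ids=[str(s) for s in df.index],
        snp_ids=[str(s) for s in df.columns],
        missing=missing if missing.any() else None,
    )


def _read_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    snp_ids: list[str] = []
    risk_alleles: list[str] = []
    columns: list[np.ndarray] = []
    miss_cols: list[np.ndarray] = []
    for variant in vcf:
        if len(variant.ALT) != 1:
            raise GenotypeValidationError(
                f"{path}: multi-allelic record at {variant.CHROM}:{variant.POS}; "
                "only biallelic SNPs are supported"
            )
        gts = np.array([gt[:2] for gt in variant.genotypes])
        missing = (gts < 0).any(axis=1)
        dos = np.where(missing, 0, (gts > 0).sum(axis=1)).astype(np.int8)
        snp_ids.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
        risk_alleles.append(variant.ALT[0])
        columns.append(dos)
        miss_cols.append(missing)
    if not columns:
        raise GenotypeValidationError(f"{path}: no variant records")
    missing = np.column_stack(miss_cols)
    return GenotypeMatrix(
        dosages=np.column_stack(columns),
        sample_ids=samples,
        snp_ids=snp_ids,
        risk_allele=risk_alleles,
        missing=missing if missing.any() else None,
    )


def write_genotypes(G: GenotypeMatrix, path, sep: str = "\t") -> None:
    values = G.dosages.astype(object)
    if G.missing is not None:
        values = np.where(G.missing, "NA", values)
    df = pd.DataFrame(values, index=G.sample_ids, columns=G.snp_ids)
    df.index.name = "sample_id"
    df.to_csv(path, sep=sep)


def drop_incomplete_samples(G: GenotypeMatrix) -> GenotypeMatrix:
    """Listwise deletion of samples with any missing genotype."""
    if G.missing is None:
        return G
    keep = np.where(~G.missing.any(axis=1))[0]
    if keep.size == 0:
        raise GenotypeValidationError("all samples have missing genotypes")
    out = G.subset_samples(keep)
    out.missing = None
    return out


# ---------------------------------------------------------------------------
# weights


def read_weights(path, align_to: list[str] | None = None) -> WeightVector:
    """Read a weight file (TSV: snp_id [, risk_allele], weight).

    With ``align_to``, the returned vector is reordered to the supplied
    SNP id list; weight-file SNPs absent from that panel are dropped with
    a warning, and panel SNPs without a weight raise an error (the score
    would silently change meaning otherwise).
    """
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str})
    if df.shape[0] == 0:
        raise WeightFileError(f"{path}: no weight records")
    if "snp_id" not in df.columns or "weight" not in df.columns:
        raise WeightFileError(f"{path}: need 'snp_id' and 'weight' columns")
    if df["snp_id"].duplicated().any():
        dups = sorted(df.loc[df["snp_id"].duplicated(), "snp_id"])
        raise WeightFileError(f"{path}: duplicate snp_id entries {dups}")
    weights = pd.to_numeric(df["weight"], errors="coerce")
    if weights.isna().any():
        bad = df.loc[weights.isna(), "snp_id"].tolist()
        raise WeightFileError(f"{path}: non-numeric weight for {bad}")
    snp_ids = df["snp_id"].tolist()
    values = weights.to_numpy(dtype=float)
    if align_to is not None:
        lookup = dict(zip(snp_ids, values))
        extra = [s for s in snp_ids if s not in set(align_to)]
        if extra:
            warnings.warn(
                f"weight file SNPs absent from genotype panel, dropped: {extra}",
                stacklevel=2,
            )
        missing = [s for s in align_to if s not in lookup]
        if missing:
            raise WeightFileError(f"panel SNPs without a weight: {missing}")
        snp_ids = list(align_to)
        values = np.array([lookup[s] for s in snp_ids])
    return WeightVector(
        weights=values, snp_ids=snp_ids, provenance="external",
        scale_note="log-OR" if "risk_allele" in df.columns else "",
    )


def write_weights(w: WeightVector, path, risk_alleles: list[str] | None = None) -> None:
    df = pd.DataFrame(
        {
            "snp_id": w.snp_ids,
            "risk_allele": risk_alleles if risk_alleles is not None else "NA",
            "weight": w.weights,
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# per-sample value tables (phenotype / exposure / GRS)


def read_value_table(path, value_column: str | None = None) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: need a 'sample_id' column")
    col = value_column or [c for c in df.columns if c != "sample_id"][0]
    return pd.Series(
        pd.to_numeric(df[col]).to_numpy(), index=df["sample_id"], name=col
    )


def write_value_table(values, sample_ids, path, value_column: str = "value") -> None:
    pd.DataFrame({"sample_id": sample_ids, value_column: np.asarray(values)}).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Validated run configuration (YAML-loadable).

    ``split_ratio`` is the train:test balance for the
    interaction-training regime, e.g. (1, 1) for Dudbridge's even split.
    The ``simulation`` block is passed through to
    :class:`grsxe.simulation.ScenarioConfig`.
    """

    weighting_method: str = "interaction-training"
    coding: str = "dominant"
    family: str = "gaussian"
    alpha: float = 0.5
    split_ratio: tuple[int, int] = (1, 1)
    cv_folds: int = 10
    seed: int = 0
    replications: int = 100
    simulation: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.weighting_method not in WEIGHTING_METHODS:
            raise ConfigError(f"unknown weighting_method {self.weighting_method!r}")
        if self.coding not in CODINGS:
            raise ConfigError(f"unknown coding {self.coding!r}")
        if self.family not in FAMILIES:
            raise ConfigError(f"unknown family {self.family!r}")
        if not 0.0 <= float(self.alpha) <= 1.0:
            raise ConfigError(f"alpha must be in [0, 1], got {self.alpha}")
        self.split_ratio = tuple(int(r) for r in self.split_ratio)
        if len(self.split_ratio) != 2 or min(self.split_ratio) < 1:
            raise ConfigError(f"split_ratio parts must be >= 1, got {self.split_ratio}")
        if self.cv_folds < 3:
            raise ConfigError("cv_folds must be >= 3")
        if self.replications < 1:
            raise ConfigError("replications must be >= 1")
        self.seed = int(self.seed)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        if "split_ratio" in raw and isinstance(raw["split_ratio"], str):
            raw["split_ratio"] = tuple(int(p) for p in raw["split_ratio"].split(":"))
        return cls(**raw)

    def config_hash(self) -> str:
        import hashlib

        payload = json.dumps(
            {k: (list(v) if isinstance(v, tuple) else v) for k, v in self.__dict__.items()},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def write_results_json(obj, path) -> None:
    def _default(x):
        if isinstance(x, (np.floating, np.integer)):
            return x.item()
        if isinstance(x, np.ndarray):
            return x.tolist()
        return str(x)

    Path(path).write_text(json.dumps(obj, indent=2, default=_default) + "\n")
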