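"""Genotype and weight containers, and the weighted genetic risk score.

A genetic risk score (GRS) condenses a panel of k single-nucleotide
polymorphisms (SNPs) into one scalar per sample,

    GRS_i = w_1 * g_i1 + ... + w_k * g_ik,

where ``g_ij`` is the risk-allele count of SNP j in sample i (0, 1 or 2)
and ``w_j`` is a per-SNP weight.  Weights may come from an external study
(typically log odds ratios of marginal genetic effects), from a penalized
regression of the outcome on the SNP panel in the study sample itself
("marginal-internal"), or from penalized SNP-by-exposure interaction
coefficients estimated on a split-off training subset
("interaction-training").  No normalizer is applied: the score is the raw
weighted allele-count sum.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

CODINGS = ("additive", "dominant", "recessive")
PROVENANCES = ("external", "marginal-internal", "interaction-training")


class GenotypeValidationError(ValueError):
    """Raised when dosages fall outside the allowed {0, 1, 2} domain."""


class AlignmentError(ValueError):
    """Raised when weight and genotype SNP panels cannot be aligned."""


@dataclass
class GenotypeMatrix:
    """An n x k allele-count matrix with SNP metadata.

    Parameters
    ----------
    dosages
        Integer matrix of shape (n, k) with entries in {0, 1, 2} (minor /
        risk-allele counts).  After dominant or recessive recoding the
        entries are in {0, 1}.
    sample_ids, snp_ids
        Row and column labels.
    maf
        Per-SNP minor allele frequency.  If omitted it is computed from
        the observed dosages (oriented to the minor allele).
    risk_allele
        Optional per-SNP risk-allele base (single character or "NA").
    missing
        Optional boolean mask of the same shape as ``dosages`` flagging
        missing entries (which are *not* imputed; see
        :func:`grsxe.io.drop_incomplete_samples`).
    coding
        The genotype coding currently applied ("additive" means raw
        0/1/2 counts).
    """

    dosages: np.ndarray
    sample_ids: list[str]
    snp_ids: list[str]
    maf: np.ndarray | None = None
    risk_allele: list[str] | None = None
    missing: np.ndarray | None = None
    coding: str = "additive"

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        if self.dosages.ndim != 2:
            raise GenotypeValidationError("dosage matrix must be 2-dimensional")
        n, k = self.dosages.shape
        if n < 1 or k < 1:
            raise GenotypeValidationError("need at least one sample and one SNP")
        if len(self.sample_ids) != n or len(self.snp_ids) != k:
            raise GenotypeValidationError("id lists do not match matrix shape")
        if len(set(self.snp_ids)) != k:
            raise GenotypeValidationError("duplicate SNP ids")
        if self.coding not in CODINGS:
            raise ValueError(f"unknown coding {self.coding!r}")
        observed = self.dosages if self.missing is None else self.dosages[~self.missing]
        bad = ~np.isin(observed, (0, 1, 2))
        if bad.any():
            raise GenotypeValidationError(
                f"dosages outside {{0,1,2}}: found {np.unique(observed[bad])!r}"
            )
        if self.maf is None and self.coding == "additive":
            self.maf = self.observed_maf()
        if self.maf is not None:
            self.maf = np.asarray(self.maf, dtype=float)

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def k(self) -> int:
        return self.dosages.shape[1]

    def observed_maf(self) -> np.ndarray:
        """Observed allele frequency per SNP, oriented to the minor allele."""
        if self.missing is None:
            freq = self.dosages.mean(axis=0) / 2.0
        else:
            masked = np.ma.MaskedArray(self.dosages, mask=self.missing)
            freq = masked.mean(axis=0).filled(np.nan) / 2.0
        return np.minimum(freq, 1.0 - freq)

    def subset_samples(self, indices: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(indices)
        return dataclasses.replace(
            self,
            dosages=self.dosages[idx],
            sample_ids=[self.sample_ids[i] for i in idx],
            missing=None if self.missing is None else self.missing[idx],
            maf=self.maf,
        )


def recode_genotypes(G: GenotypeMatrix, coding: str) -> GenotypeMatrix:
    """Apply a genotype coding to raw 0/1/2 allele counts.

    additive is the identity; dominant maps {0->0, 1->1, 2->1} (effect
    present with at least one risk allele); recessive maps
    {0->0, 1->0, 2->1}.  Dominant and recessive recodings are idempotent.
    """
    if coding not in CODINGS:
        raise ValueError(f"unknown coding {coding!r}; expected one of {CODINGS}")
    if coding == "additive":
        recoded = G.dosages
    elif coding == "dominant":
        recoded = np.minimum(G.dosages, 1)
    else:  # recessive
        if G.coding == "dominant":
            raise ValueError("cannot recode a dominant-coded matrix recessively")
        recoded = (G.dosages == 2).astype(G.dosages.dtype)
    return dataclasses.replace(G, dosages=recoded, coding=coding, maf=G.maf)


@dataclass
class WeightVector:
    """Per-SNP GRS weights with provenance.

    ``scale_note`` records the scale the weights live on (e.g. "log-OR"
    for external weights, "linear-coefficient" for gaussian fits).
    ``degenerate`` flags an all-zero vector (an over-shrunk penalized fit);
    downstream scoring of such a vector yields a constant GRS that the
    interaction test must refuse to analyse.
    """

    weights: np.ndarray
    snp_ids: list[str]
    provenance: str
    scale_note: str = ""
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 1:
            raise ValueError("weights must be 1-dimensional")
        if len(self.snp_ids) != self.weights.size:
            raise ValueError("snp_ids length does not match weights")
        if self.provenance not in PROVENANCES:
            raise ValueError(f"unknown provenance {self.provenance!r}")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")


@dataclass
class GRSVector:
    """Per-sample genetic risk scores (linear in the dosages)."""

    values: np.ndarray
    provenance: str
    coding: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


def compute_grs(G: GenotypeMatrix, w: WeightVector) -> GRSVector:
    """Weighted sum of risk-allele counts: GRS_i = sum_j w_j g_ij.

    The weight vector must be aligned to the genotype panel (same SNP ids
    in the same order); use :func:`grsxe.io.read_weights` with
    ``align_to`` to align a weight file to a panel.
    """
    if list(w.snp_ids) != list(G.snp_ids):
        extra = sorted(set(w.snp_ids) - set(G.snp_ids))
        missing = sorted(set(G.snp_ids) - set(w.snp_ids))
        raise AlignmentError(
            "weight vector not aligned to genotype panel; "
            f"weights-only SNPs: {extra}; unweighted SNPs: {missing}"
        )
    if G.missing is not None and G.missing.any():
        raise GenotypeValidationError(
            "genotype matrix contains missing entries; drop incomplete samples first"
        )
    values = G.dosages.astype(float) @ w.weights
    return GRSVector(values=values, provenance=w.provenance, coding=G.coding)


def weights_from_odds_ratios(
    odds_ratios, snp_ids: list[str], provenance: str = "external"
) -> WeightVector:
    """Convert marginal odds ratios into log-odds-ratio GRS weights.

    External weights are conventionally the natural logs of published
    per-SNP odds ratios, e.g. OR 1.49 -> ln(1.49) = 0.40 (2 dp).
    """
    ors = np.asarray(odds_ratios, dtype=float)
    if np.any(ors <= 0):
        raise ValueError("odds ratios must be positive")
    return WeightVector(
        weights=np.log(ors), snp_ids=list(snp_ids),
        provenance=provenance, scale_note="log-OR",
    )
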