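"""Derived leaf structural traits and the 6-trait PCA.

Derivations (single measured leaf per plant):

* LWC  = (wet − dry) / wet          (dimensionless, complements LDMC)
* LDMC = dry / wet                  (kg kg⁻¹)
* LMA  = dry / area                 (kg m⁻²)
* LD   = dry / (area × thickness)   (g cm⁻³)

The PCA composites the five passive traits (area, width, thickness, LWC,
density) with the active trait g_sw on the correlation matrix (traits are
standardized; their units are incommensurable). Plants missing g_sw are
excluded before the PCA.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .types import LeafTraits, ValidationError

#: Trait columns entering the PCA, in canonical order.
PCA_TRAITS = ("area_cm2", "width_mm", "thickness_mm", "lwc", "ld_g_cm3", "gsw_mol_m2_s")


def derive_traits(raw: LeafTraits) -> LeafTraits:
    """Fill the derived fields (LWC, LDMC, LMA, LD) from raw measurements.

    Raw-value validity (positive measures, dry ≤ wet) is enforced by the
    LeafTraits constructor.
    """
    wet, dry = raw.wet_mass_mg, raw.dry_mass_mg
    lwc = (wet - dry) / wet
    ldmc = dry / wet
    # mg / cm² → kg / m²: (1e-6 kg) / (1e-4 m²) = 1e-2
    lma = dry / raw.area_cm2 * 1e-2
    # dry g / (cm² × cm): mg→g is /1000, mm→cm is /10
    ld = (dry / 1000.0) / (raw.area_cm2 * raw.thickness_mm / 10.0)
    return replace(raw, lwc=lwc, ldmc=ldmc, lma_kg_m2=lma, ld_g_cm3=ld)


def derive_traits_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Vectorised :func:`derive_traits` over a raw trait table."""
    if (df["dry_mass_mg"] > df["wet_mass_mg"]).any():
        bad = df.loc[df["dry_mass_mg"] > df["wet_mass_mg"], "plant_id"].tolist()
        raise ValidationError(f"dry mass exceeds wet mass for {bad}")
    for col in ("wet_mass_mg", "dry_mass_mg", "area_cm2", "thickness_mm", "width_mm"):
        if (df[col] <= 0).any():
            bad = df.loc[df[col] <= 0, "plant_id"].tolist()
            raise ValidationError(f"non-positive {col} for {bad}")
    out = df.copy()
    out["lwc"] = (out["wet_mass_mg"] - out["dry_mass_mg"]) / out["wet_mass_mg"]
    out["ldmc"] = out["dry_mass_mg"] / out["wet_mass_mg"]
    out["lma_kg_m2"] = out["dry_mass_mg"] / out["area_cm2"] * 1e-2
    out["ld_g_cm3"] = (out["dry_mass_mg"] / 1000.0) / (
        out["area_cm2"] * out["thickness_mm"] / 10.0
    )
    return out


@dataclass
class PCAResult:
    """Correlation-matrix PCA of the six leaf traits.

    loadings: (n_traits × n_components) unit-norm eigenvectors, columns
    ordered by decreasing explained variance and sign-fixed so each
    column's largest-magnitude element is positive. contributions: squared
    loadings as percentages (each column sums to 100). scores: per-plant
    coordinates (standardized data projected on the loadings).
    """

    traits: list[str]
    loadings: pd.DataFrame
    variance_explained: np.ndarray
    contributions: pd.DataFrame
    scores: pd.DataFrame


def pca_traits(
    records: pd.DataFrame,
    traits: tuple[str, ...] = PCA_TRAITS,
    standardize: bool = True,
) -> PCAResult:
    """PCA of the leaf-trait matrix via eigendecomposition.

    ``records`` must contain the trait columns (and optionally ``plant_id``
    used to label scores); rows with any missing trait are dropped first.
    With ``standardize=False`` the covariance matrix is decomposed instead
    of the correlation matrix.
    """
    cols = list(traits)
    df = records.dropna(subset=cols)
    if len(df) < 3:
        raise ValidationError(f"need ≥3 complete records for PCA, have {len(df)}")
    X = df[cols].to_numpy(dtype=float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    zero_var = [c for c, s in zip(cols, sd) if s == 0]
    if zero_var:
        raise ValidationError(f"zero-variance trait(s): {zero_var}")
    Z = (X - mean) / sd if standardize else X - mean
    C = np.cov(Z, rowvar=False, ddof=1)
    eigval, eigvec = np.linalg.eigh(C)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    # Orient each component so its largest-magnitude loading is positive.
    for j in range(eigvec.shape[1]):
        i = np.argmax(np.abs(eigvec[:, j]))
        if eigvec[i, j] < 0:
            eigvec[:, j] *= -1
    comp_names = [f"PC{j + 1}" for j in range(eigvec.shape[1])]
    loadings = pd.DataFrame(eigvec, index=cols, columns=comp_names)
    variance = eigval / eigval.sum() * 100.0
    contributions = pd.DataFrame(
        eigvec**2 / (eigvec**2).sum(axis=0) * 100.0, index=cols, columns=comp_names
    )
    scores = pd.DataFrame(Z @ eigvec, columns=comp_names, index=df.index)
    if "plant_id" in df.columns:
        scores.insert(0, "plant_id", df["plant_id"].to_numpy())
    return PCAResult(
        traits=cols,
        loadings=loadings,
        variance_explained=variance,
        contributions=contributions,
        scores=scores,
    )
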