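"""Marker gating and phenotype assignment.

Positivity is thresholded per marker (``intensity ≥ threshold``); lineages
are then assigned by a fixed-precedence decision list:

    Tumor (CK-SOX10+)  >  Macrophage (CD68+)  >
    CD8 T_Reg (CD3+CD8+FOXP3+)  >  T_Ex (CD3+CD8+PD1+)  >
    T_Eff (CD3+CD8+PD1–)  >  CD4 T_Reg (CD3+CD4+FOXP3+)  >
    CD4 T (CD3+CD4+)  >  Other

Tumor cells additionally carry a NOS2 expression grade (weak/medium/strong;
"NOS2s" denotes the strong stratum), and COX2/PDL1 sub-flags; macrophages
carry PDL1/COX2 sub-flags.  Cells positive for both CK-SOX10 and CD3 are
resolved by precedence (tumor wins) and counted as lineage conflicts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import LINEAGES, MARKERS

#: Midpoint of the synthetic negative (1.0) / positive (5.0) intensity means.
#: NOS2's weakest positive component sits at 4.0, hence its lower default.
DEFAULT_THRESHOLDS: Mapping[str, float] = {
    **{m: 3.0 for m in MARKERS}, "NOS2": 2.5,
}


@dataclass(frozen=True)
class MarkerPanel:
    """Gating panel: per-marker thresholds and NOS2 grade cutpoints.

    ``nos2_cutpoints`` are the (weak|medium, medium|strong) intensity
    boundaries; ``None`` means per-table tertiles of NOS2+ tumor-cell
    intensity.  ``nos2s_pools_medium`` switches the NOS2s stratum from
    strong-only (default) to medium+strong.
    """

    thresholds: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    nos2_cutpoints: tuple[float, float] | None = None
    nos2s_pools_medium: bool = False

    def __post_init__(self) -> None:
        for m, t in self.thresholds.items():
            if not np.isfinite(t):
                raise ValueError(f"threshold for {m} is not finite")
        if self.nos2_cutpoints is not None:
            lo, hi = self.nos2_cutpoints
            if not lo < hi:
                raise ValueError("NOS2 cutpoints must be strictly increasing")


def call_positivity(cells: pd.DataFrame,
                    panel: MarkerPanel | None = None) -> pd.DataFrame:
    """Threshold marker intensities into boolean ``<M>_call`` columns.

    A cell is positive iff ``<M>_int ≥ threshold`` (boundary inclusive).
    Idempotent; raises ``KeyError`` naming any missing intensity column.
    """
    panel = panel or MarkerPanel()
    out = cells.copy()
    for m, thr in panel.thresholds.items():
        col = f"{m}_int"
        if col not in out.columns:
            raise KeyError(f"missing intensity column for marker {m!r} ({col})")
        out[f"{m}_call"] = out[col].to_numpy() >= thr
    return out


def assign_phenotypes(cells: pd.DataFrame,
                      panel: MarkerPanel | None = None) -> pd.DataFrame:
    """Assign one lineage label per cell plus tumor/macrophage sub-flags.

    Adds ``phenotype``, ``is_tumor``, ``is_leukocyte``, ``nos2_grade``
    (""/weak/medium/strong on NOS2+ tumor cells), ``nos2s`` and
    ``tumor_cox2`` / ``tumor_pdl1`` / ``mac_pdl1`` / ``mac_cox2`` columns.
    The count of CK-SOX10+CD3+ contradictions is stored in
    ``out.attrs["lineage_conflicts"]``.
    """
    panel = panel or MarkerPanel()
    out = cells.copy()
    c = {m: out[f"{m}_call"].to_numpy() for m in MARKERS
         if f"{m}_call" in out.columns}
    for needed in ("CKSOX10", "CD68", "CD3", "CD4", "CD8", "PD1", "FOXP3"):
        if needed not in c:
            raise KeyError(f"positivity call missing for marker {needed!r}; "
                           "run call_positivity first")
    n = len(out)
    pheno = np.full(n, "Other", dtype=object)
    unset = np.ones(n, bool)

    def take(mask: np.ndarray, label: str) -> None:
        nonlocal unset
        sel = unset & mask
        pheno[sel] = label
        unset &= ~sel

    take(c["CKSOX10"], "Tumor")
    take(c["CD68"], "Macrophage")
    take(c["CD3"] & c["CD8"] & c["FOXP3"], "CD8_TReg")
    take(c["CD3"] & c["CD8"] & c["PD1"], "TEx")
    take(c["CD3"] & c["CD8"], "TEff")
    take(c["CD3"] & c["CD4"] & c["FOXP3"], "CD4_TReg")
    take(c["CD3"] & c["CD4"], "CD4_T")

    out["phenotype"] = pheno
    out["is_tumor"] = pheno == "Tumor"
    out["is_leukocyte"] = np.isin(
        pheno, ("Macrophage", "CD8_TReg", "TEx", "TEff", "CD4_TReg", "CD4_T"))

    nos2_pos_tumor = out["is_tumor"].to_numpy() & c.get("NOS2", np.zeros(n, bool))
    grade = np.full(n, "", dtype=object)
    if nos2_pos_tumor.any():
        ints = out["NOS2_int"].to_numpy()
        if panel.nos2_cutpoints is not None:
            lo, hi = panel.nos2_cutpoints
        else:
            lo, hi = np.quantile(ints[nos2_pos_tumor], [1 / 3, 2 / 3])
        grade[nos2_pos_tumor] = np.where(
            ints[nos2_pos_tumor] < lo, "weak",
            np.where(ints[nos2_pos_tumor] < hi, "medium", "strong"))
    out["nos2_grade"] = grade
    strata = ("medium", "strong") if panel.nos2s_pools_medium else ("strong",)
    out["nos2s"] = np.isin(grade, strata)

    zeros = np.zeros(n, bool)
    out["tumor_cox2"] = out["is_tumor"].to_numpy() & c.get("COX2", zeros)
    out["tumor_pdl1"] = out["is_tumor"].to_numpy() & c.get("PDL1", zeros)
    is_mac = pheno == "Macrophage"
    out["mac_pdl1"] = is_mac & c.get("PDL1", zeros)
    out["mac_cox2"] = is_mac & c.get("COX2", zeros)

    out.attrs["lineage_conflicts"] = int((c["CKSOX10"] & c["CD3"]).sum())
    return out


def percent_cells(cells: pd.DataFrame,
                  denominator: str | np.ndarray = "all") -> pd.Series:
    """Fraction of cells per lineage over the chosen denominator.

    ``denominator`` is ``"all"``, ``"tumor"`` or a boolean mask (e.g. one
    tissue region).  An empty denominator yields NaN for every lineage —
    an undefined value, deliberately distinct from zero.
    """
    if isinstance(denominator, str):
        if denominator == "all":
            mask = np.ones(len(cells), bool)
        elif denominator == "tumor":
            mask = cells["is_tumor"].to_numpy()
        else:
            raise ValueError(f"unknown denominator {denominator!r}")
    else:
        mask = np.asarray(denominator, bool)
    total = int(mask.sum())
    if total == 0:
        return pd.Series(np.nan, index=list(LINEAGES))
    sub = cells.loc[mask, "phenotype"]
    counts = sub.value_counts()
    return pd.Series([counts.get(ph, 0) / total for ph in LINEAGES],
                     index=list(LINEAGES))


#: Per-sample metric panel used by the cohort report.
def sample_metrics(cells: pd.DataFrame) -> dict[str, float]:
    """Standard per-sample summary metrics.

    Fractions of all cells per lineage; tumor-normalized NOS2/NOS2s/COX2/PDL1
    fractions (denominator = CK-SOX10+ cells, so stromal abundance cancels);
    IFN-γ+ fraction of all cells; and the ratio biomarkers
    NOS2_Tumor/CD8, NOS2s/IFN-γ, T_Eff/CD4_T_Reg, T_Eff/PDL1_Macrophage.
    """
    n = len(cells)
    frac = percent_cells(cells, "all")
    n_tumor = int(cells["is_tumor"].sum())
    out: dict[str, float] = {f"frac_{ph}": float(frac[ph]) for ph in LINEAGES}

    def tumor_frac(col: str) -> float:
        if n_tumor == 0:
            return np.nan
        return float(cells.loc[cells["is_tumor"], col].sum() / n_tumor)

    out["nos2_tumor_frac"] = tumor_frac("NOS2_call") if "NOS2_call" in cells \
        else np.nan
    out["nos2s_frac"] = tumor_frac("nos2s")
    out["cox2_tumor_frac"] = tumor_frac("tumor_cox2")
    out["pdl1_tumor_frac"] = tumor_frac("tumor_pdl1")
    out["ifng_frac"] = float(cells["IFNG_call"].mean()) if n else np.nan
    out["mac_pdl1_frac"] = float(cells["mac_pdl1"].sum() / n) if n else np.nan
    cd8_frac = out["frac_TEff"] + out["frac_TEx"]

    def ratio(a: float, b: float) -> float:
        if not np.isfinite(a) or not np.isfinite(b) or b == 0:
            return np.nan
        return a / b

    out["ratio_nos2_cd8"] = ratio(out["nos2_tumor_frac"], cd8_frac)
    out["ratio_nos2s_ifng"] = ratio(out["nos2s_frac"], out["ifng_frac"])
    out["ratio_teff_cd4treg"] = ratio(out["frac_TEff"], out["frac_CD4_TReg"])
    out["ratio_teff_pdl1mac"] = ratio(out["frac_TEff"], out["mac_pdl1_frac"])
    return out
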