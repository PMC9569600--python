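"""Stress-tolerance indices and relative salinity performance.

The Fernandez stress-tolerance index for a genotype and trait is

    STI = (Y_p * Y_s) / Xbar_p**2

with Y_p and Y_s the genotype's trait means under control and salinity and
Xbar_p the control population mean of the trait over the retained accessions.
STI rewards genotypes that perform well under *both* conditions; it is
symmetric in Y_p and Y_s and scales with 1/Xbar_p^2.

Eight traits carry an index here: GP, MGT, ShL, RL, SL, SFW, SDW and WCP
(index columns GPTI, MGTTI, ShLTI, RLTI, SLTI, SFWTI, SDWTI, WCTI). The mean
germination time index is computed on raw MGT with no inversion, so a larger
MGTTI reflects *slower* germination under both conditions — the convention of
the screening literature this mirrors.

Relative salinity performance compares treatment population means:

    R% = 100 * (mean_salinity - mean_control) / mean_control
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "STI_TRAITS",
    "STI_COLUMNS",
    "stress_tolerance_index",
    "relative_performance",
    "build_sti_table",
    "relative_performance_table",
]

#: Traits designated for a stress-tolerance index, and their index names.
STI_TRAITS = {
    "GP": "GPTI",
    "MGT": "MGTTI",
    "ShL": "ShLTI",
    "RL": "RLTI",
    "SL": "SLTI",
    "SFW": "SFWTI",
    "SDW": "SDWTI",
    "WCP": "WCTI",
}
STI_COLUMNS = list(STI_TRAITS.values())


def stress_tolerance_index(yp, ys, xbar_p) -> np.ndarray:
    """Fernandez STI = (Y_p * Y_s) / Xbar_p^2."""
    xbar_p = np.asarray(xbar_p, dtype=float)
    if np.any(xbar_p == 0):
        raise ValueError("control population mean is zero; STI undefined")
    return np.asarray(yp, dtype=float) * np.asarray(ys, dtype=float) / xbar_p**2


def relative_performance(mean_control: float, mean_salinity: float) -> float:
    """R%: percent change of the salinity mean relative to the control mean."""
    if mean_control == 0:
        raise ValueError("control mean is zero; relative performance undefined")
    return 100.0 * (mean_salinity - mean_control) / mean_control


def build_sti_table(means: pd.DataFrame) -> pd.DataFrame:
    """Per-accession stress-tolerance indices for the eight designated traits.

    Parameters
    ----------
    means
        Accession x treatment trait means (output of
        :func:`saltscan.germination.accession_treatment_means`).

    Returns
    -------
    DataFrame with one row per accession holding the eight index columns.
    Accessions lacking either treatment are dropped (count logged). The
    control population mean Xbar_p is taken over the retained accessions.
    """
    wide = means.pivot(index="accession", columns="treatment", values=list(STI_TRAITS))
    have_both = pd.Series(True, index=wide.index)
    for trait in STI_TRAITS:
        for treatment in ("control", "salinity"):
            if (trait, treatment) not in wide.columns:
                raise ValueError(f"treatment {treatment!r} missing for trait {trait}")
        have_both &= wide[(trait, "control")].notna() & wide[(trait, "salinity")].notna()
    n_dropped = int((~have_both).sum())
    if n_dropped:
        logger.info("dropped %d accessions missing a treatment mean", n_dropped)
    wide = wide.loc[have_both]

    out = pd.DataFrame(index=wide.index)
    for trait, index_name in STI_TRAITS.items():
        yp = wide[(trait, "control")].to_numpy()
        ys = wide[(trait, "salinity")].to_numpy()
        out[index_name] = stress_tolerance_index(yp, ys, yp.mean())
    return out.reset_index()


def relative_performance_table(means: pd.DataFrame, traits: list[str]) -> pd.DataFrame:
    """R% per trait from accession-mean population means, 2-decimal reporting."""
    rows = []
    for trait in traits:
        by_treatment = means.groupby("treatment")[trait].mean()
        rows.append(
            {
                "trait": trait,
                "mean_control": by_treatment["control"],
                "mean_salinity": by_treatment["salinity"],
                "r_pct": round(
                    relative_performance(by_treatment["control"], by_treatment["salinity"]), 2
                ),
            }
        )
    return pd.DataFrame(rows)
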