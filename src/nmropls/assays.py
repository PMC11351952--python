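"""Small assay computations: OGTT AUC and comparative-Ct expression folds."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohortsim import OGTT_TIMEPOINTS, CtTable

__all__ = ["ogtt_auc", "ogtt_auc_table", "ddct_folds"]


def ogtt_auc(glucose, times=OGTT_TIMEPOINTS, incremental: bool = False) -> float:
    """Glucose-tolerance AUC normalized to the basal glucose level.

    Default: trapezoidal AUC over the test period divided by the 0-min
    (basal) glucose value — units of minutes, invariant to rescaling the
    whole curve.  With ``incremental=True`` the incremental AUC (area
    between the curve and the basal level, mmol/L·min) is returned instead.
    """
    g = np.asarray(glucose, dtype=float)
    t = np.asarray(times, dtype=float)
    if g.shape != t.shape or g.size < 2:
        raise ValueError("glucose and times must be equal-length (>= 2) vectors")
    if np.any(np.diff(t) <= 0):
        raise ValueError("timepoints must be strictly increasing")
    if np.any(~np.isfinite(g)) or np.any(g <= 0):
        raise ValueError("glucose values must be positive")
    baseline = g[0]
    auc = float(np.trapezoid(g, t))
    if incremental:
        return auc - baseline * float(t[-1] - t[0])
    return auc / baseline


def ogtt_auc_table(ogtt: pd.DataFrame, incremental: bool = False) -> pd.DataFrame:
    """Per-sample normalized AUC from an OGTT table (``glc_*`` columns)."""
    cols = [f"glc_{int(t)}" for t in OGTT_TIMEPOINTS]
    missing = [c for c in cols if c not in ogtt.columns]
    if missing:
        raise ValueError(f"OGTT table is missing columns {missing}")
    auc = [
        ogtt_auc(row[cols].to_numpy(dtype=float), incremental=incremental)
        for _, row in ogtt.iterrows()
    ]
    return ogtt[["sample_id", "group"]].assign(auc=auc)


def ddct_folds(ct: CtTable, control_group: str) -> pd.DataFrame:
    """Comparative-Ct (ΔΔCt) expression folds relative to a control group.

    ΔCt = Ct_target − mean(reference Cts); ΔΔCt = ΔCt − mean(control-group
    ΔCt); fold = 2^(−ΔΔCt).  The control group's folds have geometric mean 1
    by construction, and a global cycle shift of the whole table cancels.
    Returns a table with one fold column per target gene.
    """
    df = ct.frame
    if control_group not in set(df["group"]):
        raise ValueError(f"control group {control_group!r} not in table")
    for gene in (*ct.reference_genes, *ct.target_genes):
        if df[gene].isna().any():
            bad = df.loc[df[gene].isna(), "sample_id"].tolist()
            raise ValueError(f"missing Ct for gene {gene!r} in samples {bad}")
    ref = df[list(ct.reference_genes)].mean(axis=1)
    out = df[["sample_id", "group"]].copy()
    ctrl_mask = (df["group"] == control_group).to_numpy()
    for gene in ct.target_genes:
        dct = df[gene] - ref
        ddct = dct - float(dct[ctrl_mask].mean())
        out[gene] = np.power(2.0, -ddct)
    return out
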