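"""Mass univariate signature x drug interaction screen.

For every (SBS signature, drug) pair with enough observations, LN_IC50 is
regressed on signature activity across cell lines (simple univariate OLS,
pooled pan-cancer by default; a per-tissue stratified mode is available).
Each pair yields the Pearson correlation r, the OLS slope (log-uM per
activity unit), and a two-sided p-value from

    t = r * sqrt((n - 2) / (1 - r^2))   ~  t_{n-2}  under the null.

Pairs are flagged significant at raw p < alpha (default 0.01), the filter
used for the interaction atlas; Benjamini-Hochberg q-values can be
appended but never change the headline flag.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import EmptyOutputError, InvalidInputError, SchemaError

__all__ = ["screen", "adjust_fdr", "atlas_export"]

log = logging.getLogger(__name__)

ATLAS_COLUMNS = ["signature", "drug", "n", "r", "slope", "p", "significant"]


def _pair_stats(activity: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Pearson r, OLS slope, and two-sided p for one pair."""
    n = len(y)
    ax = activity - activity.mean()
    ay = y - y.mean()
    sxx = float(ax @ ax)
    syy = float(ay @ ay)
    sxy = float(ax @ ay)
    r = sxy / np.sqrt(sxx * syy)
    r = float(np.clip(r, -1.0, 1.0))
    slope = sxy / sxx
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return r, float(slope), p


def screen(master: pd.DataFrame, signatures: pd.DataFrame,
           alpha: float = 0.01, min_n: int = 20,
           stratify_by_tissue: bool = False) -> pd.DataFrame:
    """Run the screen over every testable (signature, drug) pair.

    ``master`` needs CELL_LINE_NAME, DRUG_NAME, LN_IC50 (and TCGA_DESC when
    stratifying); ``signatures`` is keyed on CELL_LINE_NAME with one column
    per signature.  Pairs with fewer than ``min_n`` observations or zero
    activity variance are skipped (logged).  Results are sorted by p-value
    (ties by signature then drug), so the output is invariant to the row
    order of the input.
    """
    for col in ("CELL_LINE_NAME", "DRUG_NAME", "LN_IC50"):
        if col not in master.columns:
            raise SchemaError(f"master table missing {col}")
    if "CELL_LINE_NAME" not in signatures.columns:
        raise SchemaError("signatures table missing CELL_LINE_NAME")
    if not 0.0 < alpha < 1.0:
        raise InvalidInputError("alpha must be in (0, 1)")
    if min_n < 3:
        raise InvalidInputError("min_n must be >= 3")

    sig_cols = [c for c in signatures.columns if c != "CELL_LINE_NAME"]
    joined = master.merge(signatures, on="CELL_LINE_NAME", how="inner",
                          validate="m:1")
    if joined.empty:
        raise EmptyOutputError("no master rows match the signature table")

    if stratify_by_tissue:
        if "TCGA_DESC" not in joined.columns:
            raise SchemaError("stratified screen requires TCGA_DESC in master")
        group_cols = ["TCGA_DESC", "DRUG_NAME"]
    else:
        group_cols = ["DRUG_NAME"]

    rows = []
    n_skipped = 0
    for keys, grp in joined.groupby(group_cols, sort=True):
        keys = keys if isinstance(keys, tuple) else (keys,)
        drug = keys[-1]
        y = grp["LN_IC50"].to_numpy(dtype=float)
        for sig in sig_cols:
            a = grp[sig].to_numpy(dtype=float)
            ok = np.isfinite(a) & np.isfinite(y)
            a_ok, y_ok = a[ok], y[ok]
            if len(a_ok) < min_n:
                n_skipped += 1
                continue
            if np.ptp(a_ok) == 0.0 or np.ptp(y_ok) == 0.0:
                log.debug("skipping %s/%s: zero variance", sig, drug)
                n_skipped += 1
                continue
            r, slope, p = _pair_stats(a_ok, y_ok)
            row = {"signature": sig, "drug": drug, "n": len(a_ok),
                   "r": r, "slope": slope, "p": p, "significant": p < alpha}
            if stratify_by_tissue:
                row["tissue"] = keys[0]
            rows.append(row)
    if n_skipped:
        log.info("screen skipped %d pairs (too few observations or zero variance)",
                 n_skipped)
    if not rows:
        raise EmptyOutputError("no testable (signature, drug) pairs")
    out = pd.DataFrame(rows)
    sort_cols = ["p", "signature", "drug"]
    return out.sort_values(sort_cols, kind="mergesort").reset_index(drop=True)


def adjust_fdr(results: pd.DataFrame) -> pd.DataFrame:
    """Append Benjamini-Hochberg step-up q-values; the raw-p significance
    flags are left untouched."""
    if results.empty:
        raise InvalidInputError("no screen results to adjust")
    out = results.copy()
    out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out


def atlas_export(results: pd.DataFrame, outdir: str | Path,
                 ) -> dict[str, Path]:
    """Write the full atlas and the significant subset as CSV.

    Returns the paths written; the significant file keeps its header even
    when no pair passes the filter.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cols = [c for c in ATLAS_COLUMNS + ["q", "tissue"] if c in results.columns]
    full = outdir / "interaction_atlas.csv"
    sig = outdir / "interaction_atlas_significant.csv"
    results[cols].to_csv(full, index=False)
    results.loc[results["significant"], cols].to_csv(sig, index=False)
    log.info("atlas: %d pairs tested, %d significant",
             len(results), int(results["significant"].sum()))
    return {"atlas": full, "significant": sig}
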