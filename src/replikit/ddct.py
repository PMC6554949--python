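"""Relative quantification of qPCR targets by the delta-delta-Ct method.

Organelle genome copy number is measured relative to a single-copy nuclear
reference amplicon and to a control genotype (wild type).  Within each
genotype and replicate, dCt = Ct(target) - Ct(reference); the genotype
effect is ddCt = mean dCt(genotype) - mean dCt(control), and the fold
change is 2^(-ddCt), assuming a doubling of product every cycle.
Confidence intervals are computed on the ddCt (log2) scale from the
replicate spread and then exponentiated, so they are asymmetric around the
ratio as is standard for this assay.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("genotype", "target", "replicate", "ct")


def read_ct_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = set(REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"Ct CSV missing column(s): {sorted(missing)}")
    return df


def _delta_ct(df: pd.DataFrame, reference_target: str) -> pd.DataFrame:
    """Per (genotype, target, replicate) dCt against the reference target."""
    ref = (
        df[df["target"] == reference_target]
        .set_index(["genotype", "replicate"])["ct"]
        .rename("ct_ref")
    )
    if ref.index.has_duplicates:
        ref = ref.groupby(level=[0, 1]).mean()
    tgt = df[df["target"] != reference_target]
    merged = tgt.join(ref, on=["genotype", "replicate"])
    if merged["ct_ref"].isna().any():
        bad = merged.loc[merged["ct_ref"].isna(), ["genotype", "replicate"]]
        raise ValueError(
            "missing reference-target Ct for replicate(s): "
            + ", ".join(f"{g}/{r}" for g, r in bad.itertuples(index=False))
        )
    merged = merged.assign(dct=merged["ct"] - merged["ct_ref"])
    return merged[["genotype", "target", "replicate", "dct"]]


def relative_quantity(
    ct: pd.DataFrame,
    reference_target: str,
    control_genotype: str,
    conf_level: float = 0.95,
) -> pd.DataFrame:
    """Fold change 2^(-ddCt) per (genotype, target), with confidence interval.

    ``ct`` columns: genotype, target, replicate, ct.  Replicate dCt values
    are paired within (genotype, replicate); the interval on ddCt is a
    Welch two-sample t-interval between the genotype's and the control's
    replicate dCt values, exponentiated to the ratio scale.  The control
    genotype's own ratio is 1 by construction and carries no interval.
    With a single replicate the ratio is still reported, with a warning and
    NaN interval bounds.
    """
    missing = set(REQUIRED_COLUMNS) - set(ct.columns)
    if missing:
        raise ValueError(f"Ct table missing column(s): {sorted(missing)}")
    if not np.isfinite(ct["ct"]).all() or (ct["ct"] <= 0).any():
        raise ValueError("Ct values must be finite and > 0")
    if reference_target not in set(ct["target"]):
        raise ValueError(f"reference target {reference_target!r} absent from table")
    if control_genotype not in set(ct["genotype"]):
        raise ValueError(f"control genotype {control_genotype!r} absent from table")

    dct = _delta_ct(ct, reference_target)
    alpha = 1.0 - conf_level
    records = []
    for (genotype, target), grp in dct.groupby(["genotype", "target"], sort=False):
        ctrl = dct[(dct["genotype"] == control_genotype) & (dct["target"] == target)]
        if ctrl.empty:
            raise ValueError(
                f"control genotype has no data for target {target!r}"
            )
        x = grp["dct"].to_numpy(float)
        y = ctrl["dct"].to_numpy(float)
        ddct = float(x.mean() - y.mean())
        ratio = 2.0 ** (-ddct)
        lo = hi = np.nan
        if genotype == control_genotype:
            ddct, ratio = 0.0, 1.0
        elif len(x) < 2 or len(y) < 2:
            warnings.warn(
                f"{genotype}/{target}: a single replicate; "
                "reporting ratio without confidence interval",
                stacklevel=2,
            )
        else:
            vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
            se = np.sqrt(vx + vy)
            if se == 0:
                lo = hi = ratio
            else:
                df_w = (vx + vy) ** 2 / (
                    vx**2 / (len(x) - 1) + vy**2 / (len(y) - 1)
                )
                tcrit = stats.t.ppf(1.0 - alpha / 2.0, df_w)
                lo = 2.0 ** (-(ddct + tcrit * se))
                hi = 2.0 ** (-(ddct - tcrit * se))
        records.append(
            {
                "genotype": genotype,
                "target": target,
                "n_replicates": len(x),
                "ddct": ddct,
                "ratio": ratio,
                "ci_low": lo,
                "ci_high": hi,
            }
        )
    return pd.DataFrame(records)


def per_organelle_means(
    result: pd.DataFrame, organelle_of: dict[str, str]
) -> pd.DataFrame:
    """Average per-target ratios within organelle groups (geometric mean).

    ``organelle_of`` maps target names to group labels (e.g. three
    mitochondrial and three plastid amplicons).  Ratios are averaged on the
    log2 scale, matching the scale on which the ddCt statistics live.
    """
    df = result.copy()
    df["organelle"] = df["target"].map(organelle_of)
    df = df.dropna(subset=["organelle"])
    out = (
        df.assign(log2_ratio=np.log2(df["ratio"]))
        .groupby(["genotype", "organelle"], sort=False)["log2_ratio"]
        .mean()
        .rename("mean_log2_ratio")
        .reset_index()
    )
    out["ratio"] = 2.0 ** out["mean_log2_ratio"]
    return out[["genotype", "organelle", "ratio", "mean_log2_ratio"]]


def write_results_tsv(result: pd.DataFrame, path: str | Path) -> None:
    result.to_csv(path, sep="\t", index=False, float_format="%.6g")
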