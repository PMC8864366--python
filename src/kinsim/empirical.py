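"""Estimation of cooperation/competition pressures from ethnographic tables.

Pipeline for SCCS-style data (one row per society, one column per
ordinal ethnographic variable):

1. z-score every variable over its non-missing entries (mean 0,
   variance 1), dropping constant columns;
2. align signs so that larger values mean stronger pressure, and average
   each society's available variables mapped to the cooperation pressure
   into ``dc_tilde`` and those mapped to the competition pressure into
   ``dm_tilde`` (missing cells are simply left out of the average);
3. shift each estimate so its minimum over societies is zero (the model
   pressures are non-negative; only relative magnitudes are
   identified);
4. rank variables by how well they separate kinship structures: for
   every unordered pair of structure classes, code membership 0/1 and
   compute the Spearman rank correlation with each variable over
   pairwise-complete observations, then average |rho| over pairs.

The default variable -> pressure mapping covers the ten indicator
variables of societal unity/external conflict (cooperation, d_c) and
intra-societal conflict/adultery attitudes (competition, d_m).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

__all__ = [
    "VariableMapping",
    "DEFAULT_MAPPING",
    "normalize_variables",
    "estimate_dc_dm",
    "spearman_pair_correlations",
    "empirical_phase_table",
    "read_mapping",
]

STRUCTURE_LABELS = (
    "clan_endogamy",
    "dual_organization",
    "generalized_exchange",
    "restricted_exchange",
)
_ID_COLS = ("society_id", "structure", "descent")


@dataclass(frozen=True)
class VariableMapping:
    """One ethnographic variable assigned to a model pressure with a sign."""

    variable: str
    target: str  # "d_c" or "d_m"
    sign: int = 1

    def __post_init__(self) -> None:
        if self.target not in ("d_c", "d_m"):
            raise ValueError("target must be 'd_c' or 'd_m'")
        if self.sign not in (1, -1):
            raise ValueError("sign must be +1 or -1")


#: cooperation-pressure indicators (social unity, inter-society conflict)
#: and competition-pressure indicators (intra-society conflict, adultery
#: attitudes); signs are + because larger coded values mean more pressure.
DEFAULT_MAPPING: tuple[VariableMapping, ...] = (
    VariableMapping("tributary_payments_or_taxation", "d_c"),
    VariableMapping("violence_against_other_ethnic_groups", "d_c"),
    VariableMapping("external_warfare", "d_c"),
    VariableMapping("hostility_towards_other_ethnic_groups", "d_c"),
    VariableMapping("cross_cutting_ties", "d_c"),
    VariableMapping("conflict_within_the_society", "d_m"),
    VariableMapping("violence_within_the_society", "d_m"),
    VariableMapping("disapproval_of_rape", "d_m"),
    VariableMapping("disapproval_of_premarital_sex", "d_m"),
    VariableMapping("disapproval_of_incest", "d_m"),
)


def _variable_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in _ID_COLS]


def normalize_variables(table: pd.DataFrame,
                        variables: list[str] | None = None) -> pd.DataFrame:
    """z-score each variable over non-missing entries; drop constant ones.

    Mean 0 and variance 1 (population variance) hold exactly over the
    non-missing entries of every retained column; missing cells stay
    missing.
    """
    out = table.copy()
    if variables is None:
        variables = _variable_columns(out)
    for col in variables:
        x = out[col].astype(float)
        sd = x.std(ddof=0, skipna=True)
        if not np.isfinite(sd) or sd == 0 or x.notna().sum() < 2:
            warnings.warn(f"dropping constant or empty variable {col!r}")
            out = out.drop(columns=[col])
            continue
        out[col] = (x - x.mean(skipna=True)) / sd
    return out


def estimate_dc_dm(table: pd.DataFrame,
                   mapping: tuple[VariableMapping, ...] = DEFAULT_MAPPING,
                   ) -> pd.DataFrame:
    """Per-society pressure estimates from a normalized table.

    Signed averages of the available mapped variables per target,
    shifted so each estimate's minimum over societies is 0.  Societies
    with no available variable for a target get a missing estimate.
    Returns columns society_id, dc_tilde, dm_tilde.
    """
    est = {"d_c": [], "d_m": []}
    for target in ("d_c", "d_m"):
        maps = [m for m in mapping if m.target == target and m.variable in table.columns]
        if not maps:
            warnings.warn(f"no mapped variables for {target} present; estimate is missing")
            est[target] = np.full(len(table), np.nan)
            continue
        signed = np.column_stack(
            [m.sign * table[m.variable].astype(float).to_numpy() for m in maps]
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
            est[target] = np.nanmean(signed, axis=1)
    out = pd.DataFrame({
        "society_id": table["society_id"].to_numpy()
        if "society_id" in table.columns else np.arange(len(table)),
        "dc_tilde": est["d_c"],
        "dm_tilde": est["d_m"],
    })
    for col in ("dc_tilde", "dm_tilde"):
        vals = out[col].to_numpy()
        if np.isfinite(vals).any():
            out[col] = vals - np.nanmin(vals)
    return out


def spearman_pair_correlations(
    table: pd.DataFrame,
    structure_col: str = "structure",
    variables: list[str] | None = None,
    min_pair_size: int = 3,
) -> pd.DataFrame:
    """Rank variables by mean |Spearman rho| over structure-class pairs.

    For each unordered pair of structure classes present, societies of
    the two classes are coded 0/1 and the Spearman rank correlation with
    each variable is computed over pairwise-complete observations (ties
    mid-ranked).  Pairs with fewer than ``min_pair_size`` societies are
    skipped.  Returns variable, mean_abs_rho and n_pairs, sorted by
    descending mean absolute correlation.
    """
    if variables is None:
        variables = _variable_columns(table)
    labels = table[structure_col]
    classes = sorted(c for c in labels.dropna().unique() if c != "excluded")
    if len(classes) < 2:
        raise ValueError("need at least two structure classes")
    rows = []
    for var in variables:
        rhos = []
        for i in range(len(classes)):
            for j in range(i + 1, len(classes)):
                mask = labels.isin([classes[i], classes[j]])
                sub = table.loc[mask]
                if len(sub) < min_pair_size:
                    warnings.warn(
                        f"pair ({classes[i]}, {classes[j]}) has <{min_pair_size} societies; skipped"
                    )
                    continue
                x = sub[var].astype(float)
                y = (sub[structure_col] == classes[j]).astype(float)
                ok = x.notna()
                if ok.sum() < min_pair_size or y[ok].nunique() < 2:
                    continue
                rho = spearmanr(x[ok], y[ok]).statistic
                if np.isfinite(rho):
                    rhos.append(abs(rho))
        rows.append({"variable": var,
                     "mean_abs_rho": float(np.mean(rhos)) if rhos else np.nan,
                     "n_pairs": len(rhos)})
    out = pd.DataFrame(rows).sort_values("mean_abs_rho", ascending=False,
                                         ignore_index=True)
    return out


def empirical_phase_table(estimates: pd.DataFrame,
                          structure_labels: pd.Series | np.ndarray,
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-society phase scatter plus per-structure ratio summaries.

    Returns ``(scatter, summary)``: scatter holds one row per society
    with (dc_tilde, dm_tilde, structure); summary holds, per structure,
    the society count and the median of ``dm_tilde / dc_tilde``
    (computed over societies with positive dc_tilde).
    """
    scatter = estimates.copy()
    scatter["structure"] = np.asarray(structure_labels)
    rows = []
    for s, grp in scatter.groupby("structure"):
        dc = grp["dc_tilde"].to_numpy()
        dm = grp["dm_tilde"].to_numpy()
        ok = np.isfinite(dc) & np.isfinite(dm) & (dc > 0)
        ratio = dm[ok] / dc[ok]
        rows.append({
            "structure": s,
            "n": int(len(grp)),
            "median_ratio": float(np.median(ratio)) if len(ratio) else np.nan,
            "median_dc": float(np.nanmedian(dc)) if len(dc) else np.nan,
            "median_dm": float(np.nanmedian(dm)) if len(dm) else np.nan,
        })
    summary = pd.DataFrame(rows)
    return scatter, summary


def read_mapping(path) -> tuple[VariableMapping, ...]:
    """Load a variable mapping from YAML ({variable: {target, sign}} or a
    list of {variable, target, sign}) or CSV (columns variable,target,sign)."""
    path = str(path)
    if path.endswith((".yml", ".yaml")):
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if isinstance(raw, dict):
            items = [{"variable": k, **v} for k, v in raw.items()]
        else:
            items = raw
    else:
        items = pd.read_csv(path).to_dict("records")
    return tuple(
        VariableMapping(str(d["variable"]), str(d["target"]), int(d.get("sign", 1)))
        for d in items
    )
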