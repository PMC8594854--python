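"""Per-copy per-generation TE mutation-rate estimation.

The core estimator is N_m / (N_SC * G): events of one type observed in a
line, divided by the ancestral copy number of the family and the number of
generations elapsed. Line-level rates for a mutation type are unweighted
means across families (with non-zero ancestral copy number); genotype,
population and overall rates are unweighted means across MA lines.
Confidence intervals come from a percentile bootstrap across lines;
rates can be corrected for the caller's false discovery rate and compared
between mutation-accumulation and extant-control lines.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .io_core import ValidationError, rng_from_seed

logger = logging.getLogger("temara")

EVENT_TYPES = ("gain01", "gain12", "loss10", "loss21")
AGGREGATE_TYPES = ("gain_all", "loss_all", "total", "net")

RATE_COLUMNS = [
    "scope", "scope_id", "family", "type",
    "n_events", "rate", "ci_low", "ci_high", "rate_adjusted",
]


def line_family_rate(n_m: int, n_sc: int, generations: int) -> float:
    """Rate = N_m / (N_SC * G), per copy per generation."""
    if n_sc <= 0 or generations <= 0:
        raise ValidationError("rate undefined: N_SC and G must be positive")
    if n_m < 0:
        raise ValidationError("event count must be >= 0")
    return n_m / (n_sc * generations)


def adjust_for_fdr(rate: float, fdr: float) -> float:
    """Multiplicative FDR correction: rate * (1 - fdr)."""
    if not (0.0 <= fdr < 1.0):
        raise ValidationError("fdr must be in [0, 1)")
    return rate * (1.0 - fdr)


def bootstrap_ci(
    values: np.ndarray,
    n_boot: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the mean of per-line values.

    Resamples lines with replacement ``n_boot`` times; returns the
    (alpha/2, 1 - alpha/2) percentiles of the resampled means. A single
    line (or identical lines) collapses the interval to a point.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 1:
        raise ValidationError("bootstrap requires >= 1 line")
    if len(values) == 1:
        return float(values[0]), float(values[0])
    rng = rng_from_seed(seed, 7)
    idx = rng.integers(0, len(values), size=(n_boot, len(values)))
    means = values[idx].mean(axis=1)
    lo, hi = np.quantile(means, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)


def line_type_rates(
    events: pd.DataFrame,
    copy_numbers: pd.DataFrame,
    lineages: pd.DataFrame,
    roles: tuple[str, ...] = ("MA",),
) -> pd.DataFrame:
    """Per-line rates for each mutation type, averaged across families.

    ``copy_numbers`` has columns (genotype_id, family_id, n_sc). For each
    line and type the rate is the unweighted mean over that genotype's
    families with n_sc > 0 of N_m / (n_sc * G); families without events
    contribute zero. Lines of other roles are ignored. Returns one row per
    line with columns for the four types plus the aggregates.
    """
    meta = lineages[lineages.role.isin(roles)]
    rows = []
    for _, line in meta.iterrows():
        fams = copy_numbers[
            (copy_numbers.genotype_id == line.genotype_id) & (copy_numbers.n_sc > 0)
        ]
        if fams.empty or line.generations <= 0:
            logger.info("skipping line %s: no usable families or G = 0", line.line_id)
            continue
        ev = events[events.line_id == line.line_id]
        counts = (
            ev.groupby(["family_id", "type"]).size().unstack(fill_value=0)
            if len(ev) else pd.DataFrame()
        )
        row = {
            "line_id": line.line_id,
            "genotype_id": line.genotype_id,
            "population_id": line.population_id,
        }
        for etype in EVENT_TYPES:
            per_family = []
            n_events = 0
            for _, fam in fams.iterrows():
                n_m = 0
                if etype in counts.columns and fam.family_id in counts.index:
                    n_m = int(counts.loc[fam.family_id, etype])
                per_family.append(line_family_rate(n_m, int(fam.n_sc), int(line.generations)))
                n_events += n_m
            row[etype] = float(np.mean(per_family))
            row[f"n_{etype}"] = n_events
        row["gain_all"] = row["gain01"] + row["gain12"]
        row["loss_all"] = row["loss10"] + row["loss21"]
        row["total"] = row["gain_all"] + row["loss_all"]
        row["net"] = row["gain_all"] - row["loss_all"]
        rows.append(row)
    return pd.DataFrame(rows)


def line_family_type_rates(
    events: pd.DataFrame,
    copy_numbers: pd.DataFrame,
    lineages: pd.DataFrame,
    roles: tuple[str, ...] = ("MA",),
) -> pd.DataFrame:
    """Per-line, per-family, per-type rates (long format)."""
    meta = lineages[lineages.role.isin(roles)]
    rows = []
    for _, line in meta.iterrows():
        fams = copy_numbers[
            (copy_numbers.genotype_id == line.genotype_id) & (copy_numbers.n_sc > 0)
        ]
        if fams.empty or line.generations <= 0:
            continue
        ev = events[events.line_id == line.line_id]
        for _, fam in fams.iterrows():
            for etype in EVENT_TYPES:
                n_m = int(((ev.family_id == fam.family_id) & (ev.type == etype)).sum())
                rows.append({
                    "line_id": line.line_id,
                    "genotype_id": line.genotype_id,
                    "population_id": line.population_id,
                    "family_id": fam.family_id,
                    "type": etype,
                    "n_events": n_m,
                    "rate": line_family_rate(n_m, int(fam.n_sc), int(line.generations)),
                })
    return pd.DataFrame(rows)


_ALL_TYPES = EVENT_TYPES + AGGREGATE_TYPES


def _scope_rows(
    scope: str,
    scope_id: str,
    lines: pd.DataFrame,
    n_boot: int,
    alpha: float,
    seed: int,
    fdr_by_type: dict[str, float] | None,
) -> list[dict]:
    rows = []
    fdr_by_type = fdr_by_type or {}
    for etype in _ALL_TYPES:
        values = lines[etype].to_numpy(dtype=float)
        rate = float(values.mean())
        lo, hi = bootstrap_ci(values, n_boot=n_boot, alpha=alpha, seed=seed)
        if etype in EVENT_TYPES:
            n_events = int(lines[f"n_{etype}"].sum())
        elif etype == "gain_all":
            n_events = int(lines.n_gain01.sum() + lines.n_gain12.sum())
        elif etype == "loss_all":
            n_events = int(lines.n_loss10.sum() + lines.n_loss21.sum())
        elif etype == "total":
            n_events = int(sum(lines[f"n_{t}"].sum() for t in EVENT_TYPES))
        else:  # net: signed count, gains minus losses
            n_events = int(
                lines.n_gain01.sum() + lines.n_gain12.sum()
                - lines.n_loss10.sum() - lines.n_loss21.sum()
            )
        adjusted = _adjusted_aggregate(lines, etype, fdr_by_type)
        rows.append({
            "scope": scope, "scope_id": scope_id, "family": "ALL", "type": etype,
            "n_events": n_events, "rate": rate, "ci_low": lo, "ci_high": hi,
            "rate_adjusted": adjusted,
        })
    return rows


def _adjusted_aggregate(
    lines: pd.DataFrame, etype: str, fdr_by_type: dict[str, float]
) -> float:
    def adj(t: str) -> float:
        return adjust_for_fdr(float(lines[t].mean()), fdr_by_type.get(t, 0.0))

    if etype in EVENT_TYPES:
        return adj(etype)
    if etype == "gain_all":
        return adj("gain01") + adj("gain12")
    if etype == "loss_all":
        return adj("loss10") + adj("loss21")
    if etype == "total":
        return sum(adj(t) for t in EVENT_TYPES)
    return adj("gain01") + adj("gain12") - adj("loss10") - adj("loss21")


def build_rate_table(
    events: pd.DataFrame,
    copy_numbers: pd.DataFrame,
    lineages: pd.DataFrame,
    roles: tuple[str, ...] = ("MA",),
    n_boot: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
    pop_agg: str = "lines-mean",
    fdr_by_type: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Aggregate rates at line, genotype, population and overall scope.

    Population rates average across all the population's MA lines by
    default; ``pop_agg='genotype-mean'`` averages genotype means instead.
    Per-family rows (overall scope) average each family's line rates
    across all lines whose genotype carries the family.
    """
    if pop_agg not in ("lines-mean", "genotype-mean"):
        raise ValidationError(f"unknown pop_agg {pop_agg!r}")
    per_line = line_type_rates(events, copy_numbers, lineages, roles)
    if per_line.empty:
        return pd.DataFrame(columns=RATE_COLUMNS)
    rows: list[dict] = []
    for _, line in per_line.iterrows():
        rows.extend(
            _scope_rows("line", line.line_id, per_line[per_line.line_id == line.line_id],
                        n_boot, alpha, seed, fdr_by_type)
        )
    for genotype, grp in per_line.groupby("genotype_id"):
        rows.extend(_scope_rows("genotype", str(genotype), grp, n_boot, alpha, seed, fdr_by_type))
    for pop, grp in per_line.groupby("population_id"):
        if pop_agg == "genotype-mean":
            grp = grp.groupby("genotype_id", as_index=False).mean(numeric_only=True)
        rows.extend(_scope_rows("population", str(pop), grp, n_boot, alpha, seed, fdr_by_type))
    rows.extend(_scope_rows("overall", "ALL", per_line, n_boot, alpha, seed, fdr_by_type))

    # per-family rows at overall scope
    per_family = line_family_type_rates(events, copy_numbers, lineages, roles)
    if not per_family.empty:
        for (family, etype), grp in per_family.groupby(["family_id", "type"]):
            values = grp.rate.to_numpy(dtype=float)
            lo, hi = bootstrap_ci(values, n_boot=n_boot, alpha=alpha, seed=seed)
            fdr = (fdr_by_type or {}).get(str(etype), 0.0)
            rows.append({
                "scope": "overall", "scope_id": "ALL", "family": str(family),
                "type": str(etype), "n_events": int(grp.n_events.sum()),
                "rate": float(values.mean()), "ci_low": lo, "ci_high": hi,
                "rate_adjusted": adjust_for_fdr(float(values.mean()), fdr),
            })
    return pd.DataFrame(rows, columns=RATE_COLUMNS)


def compare_ma_ec(ma_table: pd.DataFrame, ec_table: pd.DataFrame) -> pd.DataFrame:
    """Ratio of MA to EC rates per shared (scope, scope_id, family, type) key.

    An EC rate of zero with a positive MA rate yields an infinite ratio,
    flagged in the ``ec_zero`` column.
    """
    keys = ["scope", "scope_id", "family", "type"]
    merged = ma_table.merge(ec_table, on=keys, suffixes=("_ma", "_ec"))
    ratios = []
    for _, row in merged.iterrows():
        if row.rate_ec != 0:
            ratio = row.rate_ma / row.rate_ec
            flag = False
        elif row.rate_ma == 0:
            ratio = math.nan
            flag = False
        else:
            ratio = math.inf
            flag = True
        ratios.append((ratio, flag))
    merged["ratio"] = [r for r, _ in ratios]
    merged["ec_zero"] = [f for _, f in ratios]
    return merged[keys + ["rate_ma", "rate_ec", "ratio", "ec_zero"]]
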