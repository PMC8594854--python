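"""Spike-in validation of the event caller.

Simulates ancestor/descendant pairs with a known ground-truth event log,
pushes the synthetic read evidence through the zygosity caller, and
matches called events against the truth by (line, site, type) to estimate
the caller's false discovery rate (FDR = FP / (FP + TP)) and false
omission rate (FOR = FN / (FN + TN)) for each of the four transition
categories. Because the caller only sees ancestor-vs-final states, truth
is evaluated at the net level: the true ancestor zygosity against the
true final zygosity of each site. True-negative cells are restricted to
evaluable comparisons — site/line pairs whose true ancestral state makes
the event type possible at all (e.g. a 2->1 loss is only evaluable at
ancestrally homozygous sites).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .event_calling import EVENT_TYPES, _classify_vector, call_genotypes
from .io_core import CallingConfig, RatesConfig, ValidationError, rng_from_seed
from .synthetic_data import SimulationParams, make_ancestor, propagate_line, simulate_evidence

# ancestral zygosity that makes each event type possible
_EVALUABLE_STATE = {"gain01": 0, "gain12": 1, "loss10": 1, "loss21": 2}


@dataclass
class ConfusionByType:
    """TP/FP/FN/TN counts per event type over evaluable site x line cells."""

    counts: dict[str, dict[str, int]] = field(
        default_factory=lambda: {
            t: {"tp": 0, "fp": 0, "fn": 0, "tn": 0} for t in EVENT_TYPES
        }
    )

    def add(self, etype: str, cell: str, n: int = 1) -> None:
        self.counts[etype][cell] += n

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"type": t, **self.counts[t]} for t in EVENT_TYPES
        ]
        return pd.DataFrame(rows, columns=["type", "tp", "fp", "fn", "tn"])


def fdr_for(confusion: ConfusionByType) -> dict[str, tuple[float | None, float | None]]:
    """FDR = FP/(FP+TP) and FOR = FN/(FN+TN) per type; None when undefined."""
    out: dict[str, tuple[float | None, float | None]] = {}
    for etype, c in confusion.counts.items():
        fdr = c["fp"] / (c["fp"] + c["tp"]) if (c["fp"] + c["tp"]) > 0 else None
        for_ = c["fn"] / (c["fn"] + c["tn"]) if (c["fn"] + c["tn"]) > 0 else None
        out[etype] = (fdr, for_)
    return out


def run_spike_in(
    params: SimulationParams,
    n_replicates: int,
    seed: int,
    family_spec: dict[str, int] | None = None,
    thresholds: CallingConfig | None = None,
    n_lines: int | None = None,
    candidate_pool: int = 20_000,
) -> ConfusionByType:
    """Run simulate -> call replicates and tally the caller's confusion.

    Each replicate simulates one SC ancestor and ``n_lines`` descendant
    lines; evidence is generated over the union of ancestor sites and all
    lines' gained sites, so a site gained in one line is an evaluable
    novel-gain cell (true state 0) in every other line. Calls are matched
    to the net true transition per (line, site).
    """
    params.validate()
    thresholds = thresholds or CallingConfig()
    family_spec = family_spec or {"Gypsy": 1000}
    n_lines = n_lines or params.n_lines
    rng = rng_from_seed(seed, 11)
    confusion = ConfusionByType()

    for rep in range(n_replicates):
        rep_seed = int(rng.integers(2**31))
        ancestor = make_ancestor(
            params, family_spec, seed=rep_seed, candidate_pool=candidate_pool
        )
        lines = [
            propagate_line(ancestor, params, seed=rep_seed + 1 + i, line_id=f"ma{i}")
            for i in range(n_lines)
        ]
        union: dict[str, object] = {s.site_id: s for s in ancestor.sites}
        for res in lines:
            for s in res.sites:
                union.setdefault(s.site_id, s)
        union_sites = list(union.values())
        site_ids = [s.site_id for s in union_sites]

        sc_true = {s.site_id: int(z) for s, z in zip(ancestor.sites, ancestor.zygosity)}
        z_sc_true = np.array([sc_true.get(sid, 0) for sid in site_ids], dtype=int)

        sc_ev = simulate_evidence(union_sites, sc_true, params, seed=rep_seed + 500, line_id="sc")
        sc_calls = call_genotypes(sc_ev, thresholds).set_index("site_id")
        z_sc_called = sc_calls.z_hat.reindex(site_ids, fill_value=-1).to_numpy(dtype=int)

        for i, res in enumerate(lines):
            zmap = res.zygosity_map()
            z_true = np.array([zmap.get(sid, 0) for sid in site_ids], dtype=int)
            truth_labels = _classify_vector(z_sc_true, z_true)

            ev = simulate_evidence(
                union_sites, zmap, params, seed=rep_seed + 1000 + i, line_id=f"ma{i}"
            )
            calls = call_genotypes(ev, thresholds).set_index("site_id")
            z_called = calls.z_hat.reindex(site_ids, fill_value=-1).to_numpy(dtype=int)

            nocall = (z_sc_called == -1) | (z_called == -1)
            called_labels = np.full(len(site_ids), "nocall", dtype=object)
            ok = ~nocall
            called_labels[ok] = _classify_vector(z_sc_called[ok], z_called[ok])

            for etype in EVENT_TYPES:
                called_t = called_labels == etype
                true_t = truth_labels == etype
                evaluable = z_sc_true == _EVALUABLE_STATE[etype]
                confusion.add(etype, "tp", int((called_t & true_t).sum()))
                confusion.add(etype, "fp", int((called_t & ~true_t).sum()))
                confusion.add(etype, "fn", int((true_t & ~called_t).sum()))
                confusion.add(etype, "tn", int((evaluable & ~true_t & ~called_t).sum()))
    return confusion


def default_operating_point_fdr(
    seed: int,
    replicates: int = 10,
    n_lines: int = 10,
    n_sites: int = 2000,
) -> tuple[ConfusionByType, dict[str, tuple[float | None, float | None]]]:
    """Spike-in FDR/FOR at the default operating point (depth 50, eps 0.01).

    Transition rates are boosted (5e-3 per copy per generation over 4
    generations, half the ancestor heterozygous) so that every one of the
    four event types is spiked in at least a few hundred times; calling
    uses the default thresholds.
    """
    params = SimulationParams(
        rates=RatesConfig(u01=5e-3, u12=5e-3, u10=5e-3, u21=5e-3),
        generations=4,
        n_lines=n_lines,
        depth=50.0,
        epsilon=0.01,
        het_fraction=0.5,
        seed=seed,
    )
    confusion = run_spike_in(
        params, replicates, seed=seed, family_spec={"Gypsy": n_sites},
        thresholds=CallingConfig(),
    )
    return confusion, fdr_for(confusion)


def rate_recovery_experiment(
    seed: int,
    n_lines: int = 30,
    n_sc: int = 1000,
    generations: int = 12,
    true_rate: float = 1e-3,
    n_boot: int = 2000,
) -> dict[str, dict[str, float]]:
    """Full-pipeline recovery of known gain and loss rates.

    Simulates one genotype with ``n_sc`` heterozygous ancestral copies and
    equal novel-gain (u01) and heterozygous-loss (u10) rates, pushes the
    evidence through calling and estimation, and reports the overall
    estimate with its percentile-bootstrap CI for each rate. The ancestor
    is fully heterozygous so every copy is loss-eligible and the
    N_m / (N_SC * G) estimator targets u10 directly.
    """
    from .event_calling import call_events, sc_copy_numbers
    from .io_core import load_config
    from .rate_estimation import bootstrap_ci, line_type_rates
    from .synthetic_data import simulate_experiment

    cfg = load_config(overrides={
        "seed": seed,
        "rates": {"u01": true_rate, "u12": 0.0, "u10": true_rate, "u21": 0.0},
        "simulation": {
            "n_populations": 1, "genotypes_per_population": 1,
            "n_ma_lines": n_lines, "n_ec_lines": 0,
            "generations": generations, "het_fraction": 1.0,
            "families": {"Gypsy": n_sc}, "candidate_pool": 4000,
        },
    })
    experiment = simulate_experiment(cfg)
    events, _ = call_events(experiment.dataset, cfg.calling)
    copy_numbers = sc_copy_numbers(experiment.dataset, cfg.calling)
    per_line = line_type_rates(events, copy_numbers, experiment.dataset.lineages)
    out = {}
    for etype in ("gain01", "loss10"):
        values = per_line[etype].to_numpy(dtype=float)
        lo, hi = bootstrap_ci(values, n_boot=n_boot, seed=seed)
        out[etype] = {
            "estimate": float(values.mean()),
            "ci_low": lo, "ci_high": hi,
            "true": true_rate,
            "covered": bool(lo <= true_rate <= hi),
        }
    return out


def depth_threshold_sweep(
    depth_grid: list[float],
    threshold_grid: list[CallingConfig],
    reps: int,
    seed: int,
    base_params: SimulationParams,
    family_spec: dict[str, int] | None = None,
    detect_weight_grid: list[float] | None = None,
    n_lines: int | None = None,
) -> pd.DataFrame:
    """Full-factorial FDR/FOR sweep over depth, thresholds and detectability.

    Returns one row per (depth, thresholds, detect_weight, type) with the
    pooled confusion counts and the derived FDR/FOR; the row matching
    ``base_params``' depth and the default thresholds is flagged as the
    default operating point.
    """
    if not depth_grid or not threshold_grid:
        raise ValidationError("depth and threshold grids must be non-empty")
    detect_weight_grid = detect_weight_grid or [base_params.detect_weight]
    default = CallingConfig()
    rows = []
    for depth, thresholds, weight in itertools.product(
        depth_grid, threshold_grid, detect_weight_grid
    ):
        params = SimulationParams(
            rates=base_params.rates,
            family_rates=base_params.family_rates,
            generations=base_params.generations,
            n_lines=base_params.n_lines,
            depth=depth,
            epsilon=base_params.epsilon,
            detect_weight=weight,
            het_fraction=base_params.het_fraction,
            seed=base_params.seed,
        )
        confusion = run_spike_in(
            params, reps, seed=seed, family_spec=family_spec,
            thresholds=thresholds, n_lines=n_lines,
        )
        rates = fdr_for(confusion)
        is_default = (
            depth == base_params.depth
            and weight == base_params.detect_weight
            and (thresholds.c_min, thresholds.t0, thresholds.t2)
            == (default.c_min, default.t0, default.t2)
        )
        for etype in EVENT_TYPES:
            c = confusion.counts[etype]
            fdr, for_ = rates[etype]
            rows.append({
                "depth": depth, "c_min": thresholds.c_min,
                "t0": thresholds.t0, "t2": thresholds.t2,
                "detect_weight": weight, "type": etype,
                "fdr": fdr, "for": for_,
                "tp": c["tp"], "fp": c["fp"], "fn": c["fn"], "tn": c["tn"],
                "default_operating_point": is_default,
            })
    return pd.DataFrame(rows)
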