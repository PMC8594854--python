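"""Zygosity calling and gain/loss event classification.

Each line's per-site zygosity (0, 1, 2) is called from the presence-read
fraction f = p/(p + a): absent below ``t0``, heterozygous inside
[t0, t2], homozygous above ``t2``; sites with coverage below ``c_min``
are NoCall. Ancestor (SC) vs descendant calls are then classified into the
four scorable diploid transitions — 0->1 and 1->2 gains, 1->0 and 2->1
losses. Apparent double transitions (0->2, 2->0) and NoCall sites are
excluded and reported, never counted among the four categories.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import CallingConfig, Dataset, ValidationError

EVENT_TYPES = ("gain01", "gain12", "loss10", "loss21")

_TRANSITIONS = {
    (0, 1): "gain01",
    (1, 2): "gain12",
    (1, 0): "loss10",
    (2, 1): "loss21",
    (0, 2): "double",
    (2, 0): "double",
    (0, 0): "none",
    (1, 1): "none",
    (2, 2): "none",
}

EVENT_COLUMNS = ["line_id", "site_id", "family_id", "type", "z_sc", "z_ma"]


@dataclass(frozen=True)
class GenotypeCall:
    line_id: str
    site_id: str
    z_hat: int | None  # None = NoCall (coverage below c_min)
    f: float | None    # presence fraction p/(p+a), None when n = 0
    n: int             # total coverage


def call_genotype(
    presence_reads: int,
    absence_reads: int,
    thresholds: CallingConfig | None = None,
    line_id: str = "",
    site_id: str = "",
) -> GenotypeCall:
    """Call one site's zygosity from read counts (NoCall if n < c_min)."""
    thresholds = thresholds or CallingConfig()
    thresholds.validate()
    if presence_reads < 0 or absence_reads < 0:
        raise ValidationError("read counts must be >= 0")
    n = presence_reads + absence_reads
    if n < thresholds.c_min:
        f = presence_reads / n if n else None
        return GenotypeCall(line_id, site_id, None, f, n)
    f = presence_reads / n
    if f < thresholds.t0:
        z = 0
    elif f <= thresholds.t2:
        z = 1
    else:
        z = 2
    return GenotypeCall(line_id, site_id, z, f, n)


def call_genotypes(evidence: pd.DataFrame, thresholds: CallingConfig | None = None) -> pd.DataFrame:
    """Vectorized zygosity calls; z_hat is -1 for NoCall."""
    thresholds = thresholds or CallingConfig()
    thresholds.validate()
    p = evidence.presence_reads.to_numpy()
    a = evidence.absence_reads.to_numpy()
    n = p + a
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(n > 0, p / np.maximum(n, 1), np.nan)
    z = np.select(
        [n < thresholds.c_min, f < thresholds.t0, f <= thresholds.t2],
        [-1, 0, 1],
        default=2,
    )
    out = evidence[["line_id", "site_id"]].copy()
    out["z_hat"] = z
    out["f"] = f
    out["n"] = n
    return out


def classify_event(z_sc: int | None, z_ma: int | None) -> str:
    """Classify an SC -> descendant zygosity transition.

    Returns one of the four event types, ``none`` for identity, or
    ``double`` for apparent 0->2 / 2->0 jumps. NoCall input is a hard
    error: coverage filtering must precede classification.
    """
    if z_sc is None or z_ma is None or z_sc == -1 or z_ma == -1:
        raise ValidationError("cannot classify a NoCall genotype")
    key = (int(z_sc), int(z_ma))
    if key not in _TRANSITIONS:
        raise ValidationError(f"invalid zygosity pair {key}")
    return _TRANSITIONS[key]


def _classify_vector(z_sc: np.ndarray, z_ma: np.ndarray) -> np.ndarray:
    out = np.full(len(z_sc), "none", dtype=object)
    for (a, b), label in _TRANSITIONS.items():
        out[(z_sc == a) & (z_ma == b)] = label
    return out


def call_events(
    dataset: Dataset,
    thresholds: CallingConfig | None = None,
    roles: tuple[str, ...] = ("MA", "EC"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Call gain/loss events for every descendant line against its SC.

    Each MA/EC line is compared only to the SC of its own genotype, over
    the union of sites with evidence in either line; a site lacking an
    evidence row in one line is NoCall there. Returns (events, exclusions):
    events with one row per single-step transition, exclusions with
    per-line per-reason counts (``nocall`` = either call missing/filtered,
    ``double`` = apparent two-step transition).
    """
    thresholds = thresholds or CallingConfig()
    calls = call_genotypes(dataset.evidence, thresholds)
    family_of = dict(zip(dataset.sites.site_id, dataset.sites.family_id))
    calls_by_line = {lid: grp.set_index("site_id") for lid, grp in calls.groupby("line_id")}

    meta = dataset.lineages
    events_rows = []
    excl_rows = []
    for _, line in meta[meta.role.isin(roles)].iterrows():
        sc_id = dataset.sc_line_for(line.genotype_id)  # raises if missing
        sc = calls_by_line.get(sc_id, pd.DataFrame(columns=calls.columns).set_index("site_id"))
        desc = calls_by_line.get(line.line_id, pd.DataFrame(columns=calls.columns).set_index("site_id"))
        site_ids = sc.index.union(desc.index)
        z_sc = sc.z_hat.reindex(site_ids, fill_value=-1).to_numpy(dtype=int)
        z_ma = desc.z_hat.reindex(site_ids, fill_value=-1).to_numpy(dtype=int)

        nocall = (z_sc == -1) | (z_ma == -1)
        labels = np.full(len(site_ids), "nocall", dtype=object)
        ok = ~nocall
        labels[ok] = _classify_vector(z_sc[ok], z_ma[ok])

        for sid, label, zs, zm in zip(site_ids, labels, z_sc, z_ma):
            if label in EVENT_TYPES:
                events_rows.append(
                    (line.line_id, sid, family_of.get(sid, ""), label, int(zs), int(zm))
                )
        excl_rows.append((line.line_id, "nocall", int(nocall.sum())))
        excl_rows.append((line.line_id, "double", int((labels == "double").sum())))

    events = pd.DataFrame(events_rows, columns=EVENT_COLUMNS)
    exclusions = pd.DataFrame(excl_rows, columns=["line_id", "reason", "count"])
    return events, exclusions


def sc_copy_numbers(
    dataset: Dataset, thresholds: CallingConfig | None = None
) -> pd.DataFrame:
    """Per-genotype per-family ancestral copy number N_SC from SC calls.

    Counts SC sites called occupied (z >= 1); site-level copies, so z = 1
    and z = 2 each contribute one copy.
    """
    thresholds = thresholds or CallingConfig()
    meta = dataset.lineages
    sc_lines = meta[meta.role == "SC"]
    calls = call_genotypes(
        dataset.evidence[dataset.evidence.line_id.isin(sc_lines.line_id)], thresholds
    )
    calls = calls[calls.z_hat >= 1]
    merged = calls.merge(dataset.sites[["site_id", "family_id"]], on="site_id")
    merged = merged.merge(
        sc_lines[["line_id", "genotype_id"]], on="line_id"
    )
    counts = (
        merged.groupby(["genotype_id", "family_id"]).size().rename("n_sc").reset_index()
    )
    return counts
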