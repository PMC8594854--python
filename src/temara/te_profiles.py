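"""Long-term TE accumulation profiles.

Summaries of TE insertion polymorphism (TIP) across a panel of genotypes:
site-class counts (singletons, population-specific, shared), PCA embedding
and k-means cluster purity with respect to population of origin, mean
pairwise divergence (MPD) among copies of a TE family, and the small-sample
statistics used alongside them (goodness-of-fit G-test, Spearman rank
correlation with a t approximation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .io_core import ValidationError, rng_from_seed


@dataclass
class TIPMatrix:
    """Binary sites x genotypes presence matrix with population labels.

    ``matrix`` rows are sites, columns genotype ids, entries 0/1;
    ``populations`` maps each genotype id to its population of origin.
    """

    matrix: pd.DataFrame
    populations: dict[str, str]

    def __post_init__(self) -> None:
        values = self.matrix.to_numpy()
        if not np.isin(values, (0, 1)).all():
            raise ValidationError("TIP matrix entries must be 0 or 1")
        missing = set(self.matrix.columns) - set(self.populations)
        if missing:
            raise ValidationError(f"genotypes without population label: {sorted(missing)}")

    @property
    def genotypes(self) -> list[str]:
        return list(self.matrix.columns)

    def population_of(self, genotype: str) -> str:
        return self.populations[genotype]


@dataclass
class MPDResult:
    """Mean pairwise p-distance among aligned copies of one TE family."""

    family_id: str
    mpd: float | None
    n_copies: int
    n_pairs: int


@dataclass
class PolymorphismSummary:
    total_sites: int
    polymorphic_sites: int
    polymorphic_fraction: float
    monomorphic_present: int
    fixed_absent: int
    singletons: int
    singletons_by_population: dict[str, int]
    population_specific: int
    shared: int
    by_occupancy: pd.DataFrame = field(repr=False)


def classify_site(row: np.ndarray, populations: np.ndarray) -> str:
    """Classify one site's occupancy pattern across the genotype panel.

    Returns one of ``fixed_absent``, ``monomorphic_present``, ``singleton``,
    ``population_specific`` (occupied in >= 2 genotypes, all one population)
    or ``shared`` (occupied genotypes span >= 2 populations, not fixed).
    """
    k = int(row.sum())
    n = len(row)
    if k == 0:
        return "fixed_absent"
    if k == n:
        return "monomorphic_present"
    if k == 1:
        return "singleton"
    pops = set(populations[row.astype(bool)])
    return "population_specific" if len(pops) == 1 else "shared"


def polymorphism_summary(tip: TIPMatrix) -> PolymorphismSummary:
    """Count TIP site classes across the genotype panel.

    A site is polymorphic when occupied in at least one but not all
    genotypes (absence alleles count); fixed-present sites are monomorphic.
    """
    if tip.matrix.empty:
        raise ValidationError("TIP matrix is empty")
    values = tip.matrix.to_numpy()
    genotypes = np.array(tip.genotypes)
    pops = np.array([tip.population_of(g) for g in genotypes])
    n_genotypes = len(genotypes)

    classes = np.array([classify_site(row, pops) for row in values])
    occupancy = values.sum(axis=1)

    singleton_mask = classes == "singleton"
    singles_by_pop: dict[str, int] = {str(p): 0 for p in sorted(set(pops))}
    for row in values[singleton_mask]:
        genotype = genotypes[row.astype(bool)][0]
        singles_by_pop[tip.population_of(genotype)] += 1

    by_k = []
    for k in range(2, n_genotypes):
        in_k = occupancy == k
        by_k.append({
            "occupancy": k,
            "population_specific": int((classes[in_k] == "population_specific").sum()),
            "shared": int((classes[in_k] == "shared").sum()),
        })
    polymorphic = int(((occupancy >= 1) & (occupancy < n_genotypes)).sum())
    return PolymorphismSummary(
        total_sites=len(values),
        polymorphic_sites=polymorphic,
        polymorphic_fraction=polymorphic / len(values),
        monomorphic_present=int((classes == "monomorphic_present").sum()),
        fixed_absent=int((classes == "fixed_absent").sum()),
        singletons=int(singleton_mask.sum()),
        singletons_by_population=singles_by_pop,
        population_specific=int((classes == "population_specific").sum()),
        shared=int((classes == "shared").sum()),
        by_occupancy=pd.DataFrame(by_k, columns=["occupancy", "population_specific", "shared"]),
    )


def pca_embed(tip: TIPMatrix, n_components: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of genotypes on the centered binary TIP matrix.

    Monomorphic sites are dropped before centering; no variance scaling is
    applied (binary presence/absence data). Returns genotype coordinates
    (deterministic up to sign) and variance-explained fractions.
    """
    values = tip.matrix.to_numpy().T.astype(float)  # genotypes x sites
    if values.shape[0] < 2:
        raise ValidationError("PCA requires >= 2 genotypes")
    polymorphic = (values.sum(axis=0) > 0) & (values.sum(axis=0) < values.shape[0])
    if not polymorphic.any():
        raise ValidationError("PCA requires >= 1 polymorphic site")
    X = values[:, polymorphic]
    n_components = min(n_components, min(X.shape) - 1) or 1
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(X - X.mean(axis=0))
    frame = pd.DataFrame(
        coords,
        index=tip.genotypes,
        columns=[f"PC{i + 1}" for i in range(coords.shape[1])],
    )
    frame["population"] = [tip.population_of(g) for g in tip.genotypes]
    return frame, pca.explained_variance_ratio_


def kmeans_purity(
    tip: TIPMatrix,
    k: int,
    seed: int = 0,
    n_restarts: int = 20,
    use_embedding: bool = True,
) -> float:
    """Best-of-restarts k-means purity against population-of-origin labels.

    Purity is the fraction of genotypes assigned to a cluster whose majority
    population matches theirs: sum over clusters of the majority-label count,
    divided by the number of genotypes.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    genotypes = tip.genotypes
    if k > len(genotypes):
        raise ValidationError("k exceeds the number of genotypes")
    labels = np.array([tip.population_of(g) for g in genotypes])
    if use_embedding:
        frame, _ = pca_embed(tip, n_components=2)
        X = frame[[c for c in frame.columns if c.startswith("PC")]].to_numpy()
    else:
        X = tip.matrix.to_numpy().T.astype(float)
    rng = rng_from_seed(seed, 101)
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=int(rng.integers(2**31)))
    assignment = km.fit_predict(X)
    correct = 0
    for cluster in range(k):
        members = labels[assignment == cluster]
        if len(members):
            correct += pd.Series(members).value_counts().iloc[0]
    return correct / len(genotypes)


def pairwise_p_distance(a: str, b: str) -> float | None:
    """p-distance with pairwise gap deletion; None if no comparable columns."""
    if len(a) != len(b):
        raise ValidationError("aligned copies must have equal length")
    arr_a = np.frombuffer(a.upper().encode(), dtype="S1")
    arr_b = np.frombuffer(b.upper().encode(), dtype="S1")
    gap = np.array([g.encode() for g in "-.N"], dtype="S1")
    ok = ~(np.isin(arr_a, gap) | np.isin(arr_b, gap))
    n = int(ok.sum())
    if n == 0:
        return None
    return float((arr_a[ok] != arr_b[ok]).sum() / n)


def mean_pairwise_divergence(
    copies: list[str], family_id: str = ""
) -> MPDResult:
    """Mean pairwise p-distance (MPD) among aligned copies of a family.

    Low MPD indicates recent activity: new copies have not yet diverged by
    point mutation. Undefined (``mpd=None``) with fewer than two copies.
    """
    n = len(copies)
    n_pairs = n * (n - 1) // 2
    if n < 2:
        return MPDResult(family_id=family_id, mpd=None, n_copies=n, n_pairs=n_pairs)
    dists = []
    for i in range(n):
        for j in range(i + 1, n):
            d = pairwise_p_distance(copies[i], copies[j])
            if d is not None:
                dists.append(d)
    mpd = float(np.mean(dists)) if dists else None
    return MPDResult(family_id=family_id, mpd=mpd, n_copies=n, n_pairs=n_pairs)


def g_test(
    observed: list[int] | np.ndarray,
    expected_proportions: list[float] | np.ndarray | None = None,
) -> tuple[float, int]:
    """Goodness-of-fit G-test (log-likelihood ratio).

    G = 2 * sum O_i ln(O_i / E_i) with zero observed cells contributing 0;
    df = number of categories - 1. Expected proportions default to equal.
    """
    obs = np.asarray(observed, dtype=float)
    if (obs < 0).any():
        raise ValidationError("observed counts must be >= 0")
    if obs.sum() <= 0:
        raise ValidationError("at least one observed count must be positive")
    if expected_proportions is None:
        props = np.full(len(obs), 1.0 / len(obs))
    else:
        props = np.asarray(expected_proportions, dtype=float)
        props = props / props.sum()
    if ((props == 0) & (obs > 0)).any():
        raise ValidationError("expected proportion 0 with positive observed count")
    expected = obs.sum() * props
    nonzero = obs > 0
    g = 2.0 * float(np.sum(obs[nonzero] * np.log(obs[nonzero] / expected[nonzero])))
    return g, len(obs) - 1


def spearman_with_t(x, y) -> tuple[float, float, int]:
    """Spearman rank correlation with the t approximation.

    t = rho * sqrt((n - 2) / (1 - rho^2)), df = n - 2; |rho| = 1 yields an
    infinite t (flagged by math.inf).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValidationError("x and y must be paired")
    if len(x) < 3:
        raise ValidationError("need n >= 3 observations")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValidationError("missing values are not allowed")
    rho = float(stats.spearmanr(x, y).statistic)
    df = len(x) - 2
    if abs(abs(rho) - 1.0) < 1e-12:
        return rho, math.copysign(math.inf, rho), df
    t = rho * math.sqrt(df / (1.0 - rho * rho))
    return rho, t, df
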