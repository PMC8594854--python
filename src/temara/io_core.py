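"""Readers/writers, configuration and validation for the TE pipeline.

File formats are deliberately plain: the TE library is FASTA with
RepeatMasker-style ``name#class/family`` headers; sites, lineages and
read-evidence tables are tab-delimited UTF-8 with a required header row.
All randomness in the pipeline flows from a single configured seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("temara")

TE_CLASSES = ("DNA", "LINE", "LTR", "SINE", "RC", "Unknown")
ROLES = ("SC", "MA", "EC")

SITE_COLUMNS = ["site_id", "contig", "position", "family_id"]
LINEAGE_COLUMNS = ["line_id", "genotype_id", "population_id", "role", "generations"]
EVIDENCE_COLUMNS = ["line_id", "site_id", "presence_reads", "absence_reads"]


class ValidationError(ValueError):
    """Raised when an input file or configuration violates its contract."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TELibraryEntry:
    """One consensus sequence in a TE library.

    ``te_class`` is one of the five major TE groups or ``Unknown``; the
    family identifier is the part of the FASTA header before ``#``.
    """

    family_id: str
    te_class: str
    consensus: str

    @property
    def length(self) -> int:
        return len(self.consensus)


@dataclass(frozen=True)
class TESite:
    """A candidate or occupied TE insertion site (0-based coordinate)."""

    site_id: str
    contig: str
    position: int
    family_id: str


@dataclass(frozen=True)
class LineageMeta:
    """Metadata for one sequenced line.

    Roles: SC (starting control, the ancestor; generations 0), MA
    (mutation-accumulation descendant), EC (extant control descendant).
    """

    line_id: str
    genotype_id: str
    population_id: str
    role: str
    generations: int


@dataclass(frozen=True)
class EvidenceRecord:
    """Per-line, per-site junction-read support for presence vs absence."""

    line_id: str
    site_id: str
    presence_reads: int
    absence_reads: int


@dataclass
class Dataset:
    """Validated joint dataset of sites, lineages and read evidence."""

    sites: pd.DataFrame
    lineages: pd.DataFrame
    evidence: pd.DataFrame

    def sc_line_for(self, genotype_id: str) -> str:
        sel = self.lineages[
            (self.lineages.genotype_id == genotype_id) & (self.lineages.role == "SC")
        ]
        if len(sel) != 1:
            raise ValidationError(
                f"genotype {genotype_id!r} has {len(sel)} SC lines (expected exactly 1)"
            )
        return str(sel.line_id.iloc[0])


# ---------------------------------------------------------------------------
# TE library FASTA
# ---------------------------------------------------------------------------

def _parse_library_header(header: str) -> tuple[str, str]:
    """Split ``name#class/family`` (RepeatMasker dialect) into (name, class)."""
    if "#" in header:
        name, classification = header.split("#", 1)
        te_class = classification.split("/", 1)[0].strip()
        if te_class not in TE_CLASSES:
            te_class = "Unknown"
    else:
        name, te_class = header, "Unknown"
    return name.strip(), te_class


def read_te_library(path: str | Path) -> list[TELibraryEntry]:
    """Read a TE library FASTA with ``name#class/family`` headers.

    Bare headers default to class ``Unknown``. Duplicate family ids and
    empty sequences are hard errors.
    """
    entries: list[TELibraryEntry] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        family_id, te_class = _parse_library_header(record.id)
        seq = str(record.seq).upper()
        if not seq:
            raise ValidationError(f"empty sequence for library entry {family_id!r}")
        if family_id in seen:
            raise ValidationError(f"duplicate family_id in TE library: {family_id!r}")
        seen.add(family_id)
        entries.append(TELibraryEntry(family_id=family_id, te_class=te_class, consensus=seq))
    return entries


def write_te_library(entries: Iterable[TELibraryEntry], path: str | Path) -> None:
    """Write entries as FASTA; headers are ``family_id#te_class``."""
    records = [
        SeqRecord(Seq(e.consensus), id=f"{e.family_id}#{e.te_class}", description="")
        for e in entries
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path, columns: list[str], int_columns: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns) != columns:
        raise ValidationError(
            f"{path}: expected columns {columns}, found {list(df.columns)}"
        )
    for col in int_columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna()
        if not bad.empty and bad.any():
            # +2: one for the header row, one for 1-based file lines
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(
                f"{path}: malformed integer {df[col].iloc[row]!r} in column "
                f"{col!r} at line {row + 2}"
            )
        if (numeric % 1 != 0).any():
            row = int(np.flatnonzero((numeric % 1 != 0).to_numpy())[0])
            raise ValidationError(
                f"{path}: non-integer value {df[col].iloc[row]!r} in column "
                f"{col!r} at line {row + 2}"
            )
        df[col] = numeric.astype(int)
    return df


def read_sites(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path, SITE_COLUMNS, ["position"])
    if (df.position < 0).any():
        raise ValidationError(f"{path}: negative position")
    if df.site_id.duplicated().any():
        dup = df.site_id[df.site_id.duplicated()].iloc[0]
        raise ValidationError(f"{path}: duplicate site_id {dup!r}")
    if df.duplicated(subset=["contig", "position", "family_id"]).any():
        raise ValidationError(f"{path}: duplicate (contig, position, family_id)")
    return df


def read_lineages(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path, LINEAGE_COLUMNS, ["generations"])
    bad_roles = set(df.role) - set(ROLES)
    if bad_roles:
        raise ValidationError(f"{path}: unknown roles {sorted(bad_roles)}")
    if df.line_id.duplicated().any():
        raise ValidationError(f"{path}: duplicate line_id")
    if ((df.role == "SC") & (df.generations != 0)).any():
        raise ValidationError(f"{path}: SC lines must have generations == 0")
    if ((df.role == "MA") & (df.generations <= 0)).any():
        raise ValidationError(f"{path}: MA lines must have generations > 0")
    if (df.generations < 0).any():
        raise ValidationError(f"{path}: negative generations")
    sc_by_genotype = df[df.role == "SC"].groupby("genotype_id").size()
    for genotype in df.loc[df.role.isin(["MA", "EC"]), "genotype_id"].unique():
        if sc_by_genotype.get(genotype, 0) != 1:
            raise ValidationError(
                f"{path}: genotype {genotype!r} must have exactly one SC line"
            )
    return df


def read_evidence(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path, EVIDENCE_COLUMNS, ["presence_reads", "absence_reads"])
    if (df.presence_reads < 0).any() or (df.absence_reads < 0).any():
        raise ValidationError(f"{path}: negative read counts")
    return df


def read_tables(
    sites_path: str | Path,
    lineages_path: str | Path,
    evidence_path: str | Path,
) -> Dataset:
    """Read and cross-validate the three pipeline tables.

    Every evidence row must join an existing site and line; the first ten
    offenders are listed on failure. Row counts are reported in the log.
    """
    sites = read_sites(sites_path)
    lineages = read_lineages(lineages_path)
    evidence = read_evidence(evidence_path)

    known_sites = set(sites.site_id)
    known_lines = set(lineages.line_id)
    bad_sites = sorted(set(evidence.site_id) - known_sites)
    bad_lines = sorted(set(evidence.line_id) - known_lines)
    if bad_sites or bad_lines:
        msgs = []
        if bad_sites:
            msgs.append(f"unknown site_id: {bad_sites[:10]}")
        if bad_lines:
            msgs.append(f"unknown line_id: {bad_lines[:10]}")
        raise ValidationError("evidence references " + "; ".join(msgs))
    logger.info(
        "loaded %d sites, %d lines, %d evidence rows",
        len(sites), len(lineages), len(evidence),
    )
    return Dataset(sites=sites, lineages=lineages, evidence=evidence)


def write_tables(dataset: Dataset, out_dir: str | Path) -> dict[str, Path]:
    """Write sites/lineages/evidence TSVs; round-trips exactly via read_tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "sites": out / "sites.tsv",
        "lineages": out / "lineages.tsv",
        "evidence": out / "evidence.tsv",
    }
    dataset.sites.to_csv(paths["sites"], sep="\t", index=False)
    dataset.lineages.to_csv(paths["lineages"], sep="\t", index=False)
    dataset.evidence.to_csv(paths["evidence"], sep="\t", index=False)
    return paths


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class CallingConfig:
    """Zygosity-calling thresholds on the presence-read fraction f = p/(p+a)."""

    c_min: int = 10   # minimum total coverage for a call
    t0: float = 0.25  # f below t0 -> absent
    t2: float = 0.75  # f above t2 -> homozygous

    def validate(self) -> None:
        if self.c_min < 1:
            raise ValidationError("c_min must be >= 1")
        if not (0 < self.t0 < self.t2 < 1):
            raise ValidationError("thresholds must satisfy 0 < t0 < t2 < 1")


@dataclass
class BootstrapConfig:
    n_boot: int = 10_000
    alpha: float = 0.05
    method: str = "percentile"

    def validate(self) -> None:
        if self.n_boot < 1:
            raise ValidationError("n_boot must be >= 1")
        if not (0 < self.alpha < 1):
            raise ValidationError("alpha must be in (0, 1)")
        if self.method != "percentile":
            raise ValidationError(f"unknown bootstrap method {self.method!r}")


@dataclass
class RatesConfig:
    """Per-copy per-generation transition rates used by the simulator.

    Defaults are the MA-line per-type means observed in the motivating
    mutation-accumulation study (units: per copy per generation).
    """

    u01: float = 1.17e-5  # novel gain at an unoccupied site
    u12: float = 0.22e-5  # gain at a heterozygous site
    u10: float = 1.67e-5  # loss of a heterozygous copy
    u21: float = 0.04e-5  # loss at a homozygous site

    def validate(self) -> None:
        for name in ("u01", "u12", "u10", "u21"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"rate out of range: {name} = {v}")
        if self.u12 + self.u10 > 1.0:
            raise ValidationError("u12 + u10 exceeds 1 per generation")


@dataclass
class SimulationConfig:
    """Study design and evidence-model parameters for the synthetic generator."""

    generations: int = 12
    n_ma_lines: int = 8
    n_ec_lines: int = 2
    n_populations: int = 3
    genotypes_per_population: int = 3
    depth: float = 50.0        # mean junction reads per site (Poisson)
    epsilon: float = 0.01      # probability a read misreports the allele
    detect_weight: float = 1.0  # multiplier on the presence-read probability
    het_fraction: float = 0.3  # ancestral occupied sites that are heterozygous
    genome_size: int = 1_000_000
    n_contigs: int = 10
    candidate_pool: int = 5_000
    # realized selection-retention factors for EC lines relative to MA rates
    ec_gain_factor: float = 1.0 / 695.0
    ec_loss_factor: float = 1.0 / 7.4
    families: dict[str, int] = field(
        default_factory=lambda: {
            "Gypsy": 300, "Pao": 100, "DIRS": 40, "Penelope": 25, "I": 30,
            "hAT-Ac": 60, "P": 15, "PIF-ISL2EU": 15, "CMC-EnSpm": 30,
            "Academ-1": 10,
        }
    )

    def validate(self) -> None:
        if self.generations < 0:
            raise ValidationError("generations must be >= 0")
        if self.depth <= 0:
            raise ValidationError("depth must be > 0")
        if not (0.0 <= self.epsilon < 0.5):
            raise ValidationError("epsilon must be in [0, 0.5)")
        if not (0.0 <= self.het_fraction <= 1.0):
            raise ValidationError("het_fraction must be in [0, 1]")
        if not (0.0 <= self.detect_weight <= 1.0):
            raise ValidationError("detect_weight must be in [0, 1]")
        if any(n < 0 for n in self.families.values()):
            raise ValidationError("family copy numbers must be >= 0")


@dataclass
class Config:
    seed: int = 0
    include_unknown: bool = False
    pop_agg: str = "lines-mean"  # or "genotype-mean"
    calling: CallingConfig = field(default_factory=CallingConfig)
    bootstrap: BootstrapConfig = field(default_factory=BootstrapConfig)
    rates: RatesConfig = field(default_factory=RatesConfig)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def validate(self) -> None:
        if self.pop_agg not in ("lines-mean", "genotype-mean"):
            raise ValidationError(f"unknown pop_agg {self.pop_agg!r}")
        self.calling.validate()
        self.bootstrap.validate()
        self.rates.validate()
        self.simulation.validate()


def _update_dataclass(obj, values: Mapping, path: str) -> None:
    fields = {f.name: f for f in dataclasses.fields(obj)}
    for key, value in values.items():
        if key not in fields:
            raise ValidationError(f"unknown config key {path}{key!r}")
        current = getattr(obj, key)
        if dataclasses.is_dataclass(current) and isinstance(value, Mapping):
            _update_dataclass(current, value, f"{path}{key}.")
        else:
            setattr(obj, key, value)


def config_to_dict(config: Config) -> dict:
    return dataclasses.asdict(config)


def load_config(path: str | Path | None = None, overrides: Mapping | None = None) -> Config:
    """Load a JSON or YAML config, apply defaults, validate, and log it.

    Unknown keys are hard errors (no silent ignore); rates outside [0, 1]
    per generation are rejected.
    """
    config = Config()
    if path is not None:
        text = Path(path).read_text(encoding="utf-8")
        data = yaml.safe_load(text)  # YAML is a superset of JSON
        if data is None:
            data = {}
        if not isinstance(data, Mapping):
            raise ValidationError(f"config root must be a mapping, got {type(data).__name__}")
        _update_dataclass(config, data, "")
    if overrides:
        _update_dataclass(config, overrides, "")
    config.validate()
    logger.info("resolved config: %s", json.dumps(config_to_dict(config), sort_keys=True))
    return config


def rng_from_seed(seed: int, *spawn_key: int) -> np.random.Generator:
    """Deterministic child generator for (seed, spawn_key...)."""
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed, spawn_key=spawn_key)))
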