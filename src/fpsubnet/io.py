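"""Data model, delimited-text I/O, configuration and seeded randomness.

Conventions
-----------
* Matrices are stored as tab-delimited text with a header row and an
  index column of region ids.  Region ids are 1-based in files and
  0-based internally; the conversion happens only here.
* One master seed; per-stage generators are derived with
  :func:`stage_rng` using a documented (seed, stage-name) scheme so that
  any stage is reproducible in isolation.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("fpsubnet")

#: The eight canonical system names, in fixed display order.
SYSTEMS = (
    "visual",
    "somatomotor",
    "dorsal-attention",
    "ventral-attention",
    "limbic",
    "frontoparietal",
    "default-mode",
    "temporoparietal",
)

SUBNETWORKS = ("A", "B")

#: Default synthetic sizes for the 400-region parcellation.  The
#: frontoparietal (61), default-mode (79) and dorsal-attention (52)
#: counts are fixed; the remaining 208 regions are split across the
#: other five systems.
DEFAULT_SYSTEM_SIZES = {
    "visual": 60,
    "somatomotor": 60,
    "dorsal-attention": 52,
    "ventral-attention": 40,
    "limbic": 25,
    "frontoparietal": 61,
    "default-mode": 79,
    "temporoparietal": 23,
}


class ParcellationError(ValueError):
    """Raised for malformed region/system/subnetwork lookup tables."""


class ConfigError(ValueError):
    """Raised for malformed analysis configuration documents."""


# ---------------------------------------------------------------------------
# Parcellation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Parcellation:
    """Region -> system (-> subnetwork) lookup with stable ordering.

    Attributes
    ----------
    region_ids:
        1-based region labels, in file order.
    systems:
        System name per region (same order as ``region_ids``).
    subnetworks:
        Optional subnetwork label ("A"/"B") per region; ``None`` for
        regions outside the frontoparietal system or when no split has
        been assigned.
    """

    region_ids: np.ndarray
    systems: np.ndarray
    subnetworks: np.ndarray  # object array of "A", "B" or None

    def __post_init__(self) -> None:
        ids = np.asarray(self.region_ids)
        if len(np.unique(ids)) != len(ids):
            raise ParcellationError("duplicate region ids")
        unknown = set(self.systems) - set(SYSTEMS)
        if unknown:
            raise ParcellationError(f"unknown system name(s): {sorted(unknown)}")
        for sub, sys_name in zip(self.subnetworks, self.systems):
            if sub is not None:
                if sub not in SUBNETWORKS:
                    raise ParcellationError(f"unknown subnetwork label {sub!r}")
                if sys_name != "frontoparietal":
                    raise ParcellationError(
                        "subnetwork label on non-frontoparietal region"
                    )

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    def indices_of_system(self, system: str) -> np.ndarray:
        """0-based indices of all regions in ``system``."""
        if system not in SYSTEMS:
            raise ParcellationError(f"unknown system name: {system!r}")
        return np.flatnonzero(self.systems == system)

    def indices_of_subnetwork(self, label: str) -> np.ndarray:
        """0-based indices of frontoparietal regions in subnetwork ``label``."""
        if label not in SUBNETWORKS:
            raise ParcellationError(f"unknown subnetwork label: {label!r}")
        return np.flatnonzero(
            np.array([s == label for s in self.subnetworks], dtype=bool)
        )

    def system_sizes(self) -> dict[str, int]:
        return {s: int((self.systems == s).sum()) for s in SYSTEMS}

    def with_subnetworks(self, labels: Mapping[int, str]) -> "Parcellation":
        """Return a copy with subnetwork labels for frontoparietal regions.

        ``labels`` maps 0-based region index -> "A"/"B".
        """
        subs = np.array([None] * self.n_regions, dtype=object)
        for idx, lab in labels.items():
            subs[idx] = lab
        return Parcellation(self.region_ids.copy(), self.systems.copy(), subs)


def default_parcellation(
    system_sizes: Mapping[str, int] | None = None,
    subnetwork_split: tuple[int, int] | None = None,
) -> Parcellation:
    """Synthetic default parcellation: 400 regions, 8 systems, 30/31 split.

    Regions are laid out system-by-system in canonical order; the first
    ``subnetwork_split[0]`` frontoparietal regions get label "A", the
    rest "B".
    """
    sizes = dict(DEFAULT_SYSTEM_SIZES if system_sizes is None else system_sizes)
    missing = set(SYSTEMS) - set(sizes)
    if missing:
        raise ParcellationError(f"missing system sizes: {sorted(missing)}")
    n = sum(sizes.values())
    systems = np.concatenate(
        [np.repeat(s, sizes[s]) for s in SYSTEMS]
    ).astype(object)
    region_ids = np.arange(1, n + 1)
    subs = np.array([None] * n, dtype=object)
    fp_idx = np.flatnonzero(systems == "frontoparietal")
    if subnetwork_split is None:
        n_a = len(fp_idx) // 2
        subnetwork_split = (n_a, len(fp_idx) - n_a)
    if sum(subnetwork_split) != len(fp_idx):
        raise ParcellationError("subnetwork split does not cover the system")
    subs[fp_idx[: subnetwork_split[0]]] = "A"
    subs[fp_idx[subnetwork_split[0]:]] = "B"
    return Parcellation(region_ids, systems, subs)


def read_parcellation(path: str | Path) -> Parcellation:
    """Read a region/system/subnetwork lookup table (TSV)."""
    df = pd.read_csv(path, sep="\t", dtype={"region_id": int})
    required = {"region_id", "system"}
    if not required.issubset(df.columns):
        raise ParcellationError(f"table must have columns {sorted(required)}")
    subs: np.ndarray
    if "subnetwork" in df.columns:
        subs = np.array(
            [None if pd.isna(v) else str(v) for v in df["subnetwork"]], dtype=object
        )
    else:
        subs = np.array([None] * len(df), dtype=object)
    return Parcellation(
        df["region_id"].to_numpy(),
        df["system"].to_numpy(dtype=object),
        subs,
    )


def write_parcellation(parc: Parcellation, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "region_id": parc.region_ids,
            "system": parc.systems,
            "subnetwork": [s if s is not None else "" for s in parc.subnetworks],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Matrices
# ---------------------------------------------------------------------------


def read_matrix(path: str | Path) -> np.ndarray:
    """Read a square matrix from tab-delimited text (header row + index col)."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    mat = df.to_numpy(dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError(f"matrix in {path} is not square: shape {mat.shape}")
    if np.isnan(mat).any():
        raise ValueError(f"non-numeric or missing cells in {path}")
    return mat


def write_matrix(
    matrix: np.ndarray, path: str | Path, region_ids: Sequence[int] | None = None
) -> None:
    """Write a square matrix as tab-delimited text at full precision."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError(f"matrix is not square: shape {matrix.shape}")
    ids = (
        np.arange(1, matrix.shape[0] + 1)
        if region_ids is None
        else np.asarray(region_ids)
    )
    df = pd.DataFrame(matrix, index=ids, columns=ids)
    # %.17g round-trips IEEE doubles exactly
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_timeseries(path: str | Path) -> np.ndarray:
    """Read a regions x timepoints matrix (TSV, header row of timepoints)."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    ts = df.to_numpy(dtype=float)
    if np.isnan(ts).any():
        raise ValueError(f"missing values in timeseries {path}")
    return ts


def write_timeseries(
    ts: np.ndarray, path: str | Path, region_ids: Sequence[int] | None = None
) -> None:
    ts = np.asarray(ts, dtype=float)
    ids = np.arange(1, ts.shape[0] + 1) if region_ids is None else np.asarray(region_ids)
    df = pd.DataFrame(ts, index=ids, columns=np.arange(ts.shape[1]))
    df.to_csv(path, sep="\t", float_format="%.17g")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

CONFIG_DEFAULTS: dict[str, dict] = {
    "cohort": {
        "n_subjects": 50,
        "runs_per_subject": 2,
        "n_timepoints": 405,
        "tr": 0.72,
        "coupling_targets": None,  # generator defaults when None
        "within_subnetwork_corr": 0.25,
        "structural_motif_means": None,
        "structural_background_mean": 0.3,
        "structural_shape": 4.0,
        "behavior_effects": None,
        "noise_sd": 1.0,
        "gain_sd": 0.35,
        "coexpr_baseline": 0.4,
        "coexpr_margin": 0.15,
        "probe_noise_sd": 0.5,
        "latent_coeffs": None,
        "n_genes": 2000,
        "probes_per_gene": 2,
        "system_sizes": None,
        "subnetwork_split": None,
    },
    "wsbm": {"k": 2, "restarts": 20, "max_sweeps": 500, "variance_floor": 1e-6},
    "compare_k": {"k_values": [1, 2, 3], "n_boot": 1000},
    "boundary_control": {"pct": 95.0, "n_perm": 10000},
    "coexpression": {"n_boot": 1000, "n_perm": 200},
    "hopf": {
        "preset": "4",
        "reps": 5,
        "n_a_values": 20,
        "ablation_runs": 100,
        "census_runs": 200,
        "duration": 360.0,
        "dt": 0.01,
        "coupling_scale": 1.0,
        "ablate": False,
    },
    "stats": {"n_perm": 10000, "alpha": 0.05},
}


@dataclass
class AnalysisConfig:
    """Validated configuration: a master seed plus per-stage parameters."""

    seed: int
    stages: dict[str, dict] = field(default_factory=dict)
    paths: dict[str, str] = field(default_factory=dict)

    def stage(self, name: str) -> dict:
        """Stage parameters with defaults filled in."""
        if name not in CONFIG_DEFAULTS:
            raise ConfigError(f"unknown stage: {name!r}")
        merged = dict(CONFIG_DEFAULTS[name])
        merged.update(self.stages.get(name, {}))
        return merged


def make_config(document: Mapping) -> AnalysisConfig:
    """Build an :class:`AnalysisConfig` from a parsed JSON/YAML mapping.

    Unknown top-level or stage-level keys are rejected so that typos do
    not silently fall back to defaults.
    """
    doc = dict(document)
    if "seed" not in doc:
        raise ConfigError("config requires an integer 'seed'")
    seed = doc.pop("seed")
    if not isinstance(seed, int) or isinstance(seed, bool):
        raise ConfigError(f"seed must be an integer, got {seed!r}")
    paths = doc.pop("paths", {})
    if not isinstance(paths, dict):
        raise ConfigError("paths must be a mapping")
    stages: dict[str, dict] = {}
    for key, value in doc.items():
        if key not in CONFIG_DEFAULTS:
            raise ConfigError(f"unknown config key: {key!r}")
        if not isinstance(value, dict):
            raise ConfigError(f"stage section {key!r} must be a mapping")
        unknown = set(value) - set(CONFIG_DEFAULTS[key])
        if unknown:
            raise ConfigError(f"unknown key(s) in {key!r}: {sorted(unknown)}")
        stages[key] = dict(value)
    cfg = AnalysisConfig(seed=seed, stages=stages, paths=dict(paths))
    logger.info("loaded config with master seed %d", seed)
    return cfg


def load_config(path: str | Path) -> AnalysisConfig:
    """Load a JSON or YAML configuration document."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        doc = json.loads(text)
    else:
        doc = yaml.safe_load(text)
    if not isinstance(doc, Mapping):
        raise ConfigError("config document must be a mapping")
    return make_config(doc)


# ---------------------------------------------------------------------------
# Seeding
# ---------------------------------------------------------------------------


def stage_seed(master_seed: int, stage: str) -> np.random.SeedSequence:
    """Derive a per-stage seed sequence from the master seed.

    The stage name is hashed with CRC-32 and combined with the master
    seed in a :class:`numpy.random.SeedSequence`, so a stage can be
    rerun in isolation without replaying earlier stages.
    """
    return np.random.SeedSequence([master_seed, zlib.crc32(stage.encode())])


def stage_rng(master_seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(stage_seed(master_seed, stage))
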