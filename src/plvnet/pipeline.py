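"""Configuration, file I/O and the end-to-end pipeline.

``run_pipeline`` ties the stages together: simulate (or load) an epoched
cohort -> CAR/band-pass/Laplacian -> CMW phase extraction -> pairwise PLV
per condition and window (+ delta) -> network-scale averages -> median
split and permutation factorial ANOVA per scale/band/window, Bonferroni
threshold 0.05 / (windows x bands).  All randomness derives from one seed;
outputs are tidy CSV tables plus a JSON manifest with the config hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import connectivity as conn
from . import preprocess as pre
from . import scales as sc
from . import stats as st
from . import synthetic as syn
from .montage import load_montage, positions_for

logger = logging.getLogger("plvnet")

_EPOCH_ATTRS = ("sfreq", "t0", "subject_id")


# ---------------------------------------------------------------------------
# config
# ---------------------------------------------------------------------------

@dataclass
class StatsConfig:
    n_perm: int = 999
    alpha: float = 0.05
    m_comparisons: int | None = None  # default: n_windows(+delta) x n_bands
    unit_of_analysis: str = "subject"  # 'subject' (trial-averaged) | 'trial'
    perm_scheme: str = "subject"


@dataclass
class RunConfig:
    """Everything a pipeline run needs, serializable to YAML."""

    bands: tuple = ("alpha", "beta")
    rest_window: tuple = (0.0, 3.0)
    mi_window: tuple = (4.0, 7.5)
    local_mode: str = "star"
    aggregate: str = "samplewise"
    n_subjects: int = 12
    idio_stars: int = 1
    idio_star_size: int = 4
    idio_kappa_max: float = 4.0
    stats: StatsConfig = field(default_factory=StatsConfig)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        stats = StatsConfig(**raw.pop("stats", {}))
        cfg = cls(**raw, stats=stats)
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["bands"] = list(self.bands)
        d["rest_window"] = list(self.rest_window)
        d["mi_window"] = list(self.mi_window)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @property
    def windows(self) -> list:
        return [pre.WindowDef("rest", *self.rest_window),
                pre.WindowDef("mi", *self.mi_window)]

    @property
    def band_specs(self) -> list:
        unknown = [b for b in self.bands if b not in conn.BANDS]
        if unknown:
            raise ValueError(f"unknown bands: {unknown}")
        return [conn.BANDS[b] for b in self.bands]

    @property
    def m_comparisons_effective(self) -> int:
        if self.stats.m_comparisons is not None:
            return self.stats.m_comparisons
        # windows + delta, per band
        return (len(self.windows) + 1) * len(self.bands)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def write_epochs(epochs: pre.EpochSet, path) -> None:
    """Write an EpochSet to a self-describing HDF5 layout."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data)
        f.create_dataset("channel_names",
                         data=np.array(epochs.channel_names, dtype="S"))
        f.create_dataset("positions", data=epochs.positions)
        if epochs.labels is not None:
            f.create_dataset("labels", data=epochs.labels.astype("S"))
        if epochs.run_index is not None:
            f.create_dataset("run_index", data=epochs.run_index)
        f.attrs["sfreq"] = epochs.sfreq
        f.attrs["t0"] = epochs.t0
        f.attrs["subject_id"] = epochs.subject_id or ""


def _read_epochs_h5(path) -> pre.EpochSet:
    with h5py.File(path, "r") as f:
        for key in ("data", "channel_names", "positions"):
            if key not in f:
                raise ValueError(f"{path}: missing dataset {key!r}")
        names = tuple(n.decode() for n in f["channel_names"][()])
        labels = (np.array([x.decode() for x in f["labels"][()]])
                  if "labels" in f else None)
        return pre.EpochSet(
            data=f["data"][()], channel_names=names,
            positions=f["positions"][()], sfreq=float(f.attrs["sfreq"]),
            t0=float(f.attrs["t0"]), labels=labels,
            subject_id=str(f.attrs.get("subject_id", "")) or None,
            run_index=f["run_index"][()] if "run_index" in f else None)


def read_epochs(path, require_montage: bool = True) -> pre.EpochSet:
    """Read epochs from the HDF5 layout (or MNE FIF epochs, ``-epo.fif``).

    With ``require_montage`` the channel set must exactly cover the
    packaged 16-channel montage.
    """
    path = Path(path)
    if path.suffix == ".fif":
        import mne  # optional, only for FIF input

        ep = mne.read_epochs(path, preload=True, verbose="error")
        names = tuple(ep.ch_names)
        epochs = pre.EpochSet(
            data=ep.get_data(copy=True) * 1e6, channel_names=names,
            positions=positions_for(names), sfreq=float(ep.info["sfreq"]),
            t0=float(ep.times[0]))
    else:
        epochs = _read_epochs_h5(path)
    if require_montage:
        montage = load_montage()
        missing = [c for c in montage.index if c not in epochs.channel_names]
        if missing:
            raise ValueError(f"{path}: missing montage channels {missing}")
    return epochs


def validate_plv_table(table: pd.DataFrame) -> pd.DataFrame:
    """Schema/invariant checks for a tidy PLV table."""
    missing = set(conn.PLV_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"PLV table missing columns {sorted(missing)}")
    finite = table["plv"].to_numpy(float)
    if not np.isfinite(finite).all():
        raise ValueError("PLV table contains non-finite values")
    nondelta = table[table["window"] != "delta"]["plv"]
    if ((nondelta < 0) | (nondelta > 1)).any():
        raise ValueError("PLV outside [0, 1] for a rest/mi row")
    delta = table[table["window"] == "delta"]["plv"]
    if ((delta < -1) | (delta > 1)).any():
        raise ValueError("delta PLV outside [-1, 1]")
    return table


def write_table(table: pd.DataFrame, path) -> None:
    """Write a tidy table as UTF-8 comma-separated CSV with header."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)


def read_plv_table(path) -> pd.DataFrame:
    return validate_plv_table(pd.read_csv(path))


# ---------------------------------------------------------------------------
# stage drivers
# ---------------------------------------------------------------------------

def subject_plv_table(epochs: pre.EpochSet, config: RunConfig) -> pd.DataFrame:
    """Preprocess one subject and compute the full PLV table
    (bands x windows incl. delta x conditions x 120 pairs)."""
    clean = pre.preprocess_epochs(epochs)
    frames = []
    rest_w, mi_w = config.windows
    for band in config.band_specs:
        phases = conn.extract_phase(clean, band)
        for cond in syn.CONDITIONS:
            rest = conn.plv_matrix(phases, rest_w, cond, config.aggregate)
            mi = conn.plv_matrix(phases, mi_w, cond, config.aggregate)
            frames += [rest, mi, conn.delta_plv(mi, rest)]
    return pd.concat(frames, ignore_index=True)


def stats_tables(scale_table: pd.DataFrame, accuracy: pd.DataFrame,
                 config: RunConfig, seed=None):
    """Median split + permutation ANOVA per (scale, band, window).

    Returns ``(stats_df, assignment)``.
    """
    assignment = st.median_split(
        dict(zip(accuracy["subject_id"], accuracy["accuracy_percent"])))
    alpha_adj = st.bonferroni(config.stats.alpha,
                              config.m_comparisons_effective)
    keep = scale_table[scale_table["subject_id"].isin(assignment.group)]
    n_groups = keep.groupby(["scale", "band", "window"]).ngroups
    seeds = np.random.SeedSequence(seed).generate_state(max(n_groups, 1))
    rows = []
    k = 0
    for (scale, band, window), chunk in keep.groupby(
            ["scale", "band", "window"], sort=True):
        tbl = pd.DataFrame({
            "subject_id": chunk["subject_id"],
            "group": chunk["subject_id"].map(assignment.group),
            "hand": chunk["condition"],
            "value": chunk["mean_plv"],
        })
        results = st.perm_anova_2x2(
            tbl, n_perm=config.stats.n_perm,
            seed=int(seeds[k] % (2 ** 31)), scheme=config.stats.perm_scheme,
            alpha_adjusted=alpha_adj)
        k += 1
        for r in results:
            rows.append((scale, band, window, r.effect, r.F_obs, r.p_perm,
                         r.n_perm, alpha_adj, bool(r.significant)))
    stats_df = pd.DataFrame(rows, columns=[
        "scale", "band", "window", "effect", "F", "p",
        "n_perm", "alpha_adjusted", "significant_at_adjusted"])
    return stats_df, assignment


def run_pipeline(config: RunConfig, out_dir, seed: int = 0) -> dict:
    """End-to-end run on a simulated cohort; returns the output paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    root = np.random.SeedSequence(seed)
    sim_seed, stat_seed = (int(s.generate_state(1)[0] % (2 ** 31))
                           for s in root.spawn(2))

    logger.info("simulating cohort: %d subjects", config.n_subjects)
    cohort = syn.CohortSpec(n_subjects=config.n_subjects,
                            idio_stars=config.idio_stars,
                            idio_star_size=config.idio_star_size,
                            idio_kappa_max=config.idio_kappa_max)
    epoch_sets, accuracy = syn.generate_cohort(cohort, seed=sim_seed)
    write_table(accuracy, out / "accuracy.csv")

    frames = []
    for ep in epoch_sets:
        t0 = time.time()
        frames.append(subject_plv_table(ep, config))
        logger.info("subject %s: PLV table in %.1fs", ep.subject_id,
                    time.time() - t0)
    plv_table = validate_plv_table(pd.concat(frames, ignore_index=True))
    write_table(plv_table, out / "plv.csv")

    scale_table = sc.all_scale_averages(plv_table,
                                        local_mode=config.local_mode)
    write_table(scale_table, out / "scale_plv.csv")

    stats_df, assignment = stats_tables(scale_table, accuracy, config,
                                        seed=stat_seed)
    write_table(stats_df, out / "stats.csv")

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": int(seed),
        "n_perm": config.stats.n_perm,
        "alpha_adjusted": st.bonferroni(config.stats.alpha,
                                        config.m_comparisons_effective),
        "alpha_adjusted_display": st.format_alpha(
            st.bonferroni(config.stats.alpha,
                          config.m_comparisons_effective)),
        "n_subjects": config.n_subjects,
        "n_high": len(assignment.high),
        "n_low": len(assignment.low),
        "excluded_subjects": list(assignment.excluded),
        "rows": {"plv": len(plv_table), "scale": len(scale_table),
                 "stats": len(stats_df)},
        "runtime_s": round(time.time() - t_start, 2),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    logger.info("pipeline done in %.1fs", manifest["runtime_s"])
    return {"out_dir": str(out),
            "plv": str(out / "plv.csv"),
            "scale": str(out / "scale_plv.csv"),
            "stats": str(out / "stats.csv"),
            "accuracy": str(out / "accuracy.csv"),
            "manifest": str(out / "manifest.json")}
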