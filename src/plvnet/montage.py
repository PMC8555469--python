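"""Idealized 10-20 electrode montage on the unit sphere.

The pipeline works with 16 scalp electrodes (F3, Fz, F4, FC1, FC5, FC2, FC6,
C3, Cz, C4, CP1, CP5, CP2, CP6, T7, T8) placed at idealized 10-20 positions
projected onto a unit sphere.  The spherical-spline surface Laplacian only
needs inter-electrode angles, so idealized coordinates are sufficient; no
digitized head shape is modelled.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

#: Channel order used throughout the package (left-to-right, front-to-back).
CHANNELS_16 = (
    "F3", "Fz", "F4", "FC1", "FC5", "FC2", "FC6",
    "C3", "Cz", "C4", "CP1", "CP5", "CP2", "CP6", "T7", "T8",
)

#: Sensorimotor hub electrodes around C3 (left) and C4 (right).
LEFT_HUB = ("FC5", "FC1", "C3", "CP5", "CP1")
RIGHT_HUB = ("FC6", "FC2", "C4", "CP6", "CP2")


def load_montage(path: str | None = None) -> pd.DataFrame:
    """Load electrode unit-sphere coordinates.

    Parameters
    ----------
    path
        Optional CSV with columns ``name,x,y,z``.  Defaults to the packaged
        16-channel 10-20 montage.

    Returns
    -------
    DataFrame indexed by channel name with columns x, y, z (unit norm).
    """
    if path is None:
        ref = resources.files("plvnet.data").joinpath("montage_1020_16.csv")
        with resources.as_file(ref) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    missing = {"name", "x", "y", "z"} - set(df.columns)
    if missing:
        raise ValueError(f"montage file lacks columns: {sorted(missing)}")
    df = df.set_index("name")
    xyz = df[["x", "y", "z"]].to_numpy(float)
    norms = np.linalg.norm(xyz, axis=1)
    if np.any(norms <= 0):
        raise ValueError("montage contains a zero-length position")
    df[["x", "y", "z"]] = xyz / norms[:, None]
    return df


def positions_for(channel_names, montage: pd.DataFrame | None = None) -> np.ndarray:
    """Return an (n, 3) unit-sphere position array for the given channels."""
    if montage is None:
        montage = load_montage()
    unknown = [c for c in channel_names if c not in montage.index]
    if unknown:
        raise ValueError(f"channels not in montage: {unknown}")
    return montage.loc[list(channel_names), ["x", "y", "z"]].to_numpy(float)
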