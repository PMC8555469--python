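"""Aggregation of pairwise PLV into network scales.

Three scales localize connectivity effects:

* **global** — mean over all C(16,2) = 120 electrode pairs;
* **large** — inter-hemispheric: every pair crossing from the left
  sensorimotor hub {FC5, FC1, C3, CP5, CP1} to the right hub
  {FC6, FC2, C4, CP6, CP2} (25 pairs);
* **local_left / local_right** — intra-hemispheric: C3 (resp. C4) paired
  with each of its four hub neighbours ("star" mode, default), or all 10
  within-hub pairs ("within_hub" mode).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product

import pandas as pd

from .montage import CHANNELS_16, LEFT_HUB, RIGHT_HUB


def _canon(pair, order) -> tuple:
    a, b = pair
    if a == b:
        raise ValueError(f"self-pair {a!r} in scale definition")
    return (a, b) if order.index(a) < order.index(b) else (b, a)


@dataclass(frozen=True)
class ScaleDef:
    """Named set of unordered electrode pairs averaged into one value."""

    name: str
    pairs: tuple

    @classmethod
    def from_pairs(cls, name, pairs, order=CHANNELS_16) -> "ScaleDef":
        return cls(name, tuple(sorted(_canon(p, order) for p in pairs)))


def default_scales(order=CHANNELS_16, local_mode: str = "star") -> dict:
    """The four standard scales keyed by name."""
    global_pairs = list(combinations(order, 2))
    large = [p for p in product(LEFT_HUB, RIGHT_HUB)]
    if local_mode == "star":
        local_left = [("C3", c) for c in LEFT_HUB if c != "C3"]
        local_right = [("C4", c) for c in RIGHT_HUB if c != "C4"]
    elif local_mode == "within_hub":
        local_left = list(combinations(LEFT_HUB, 2))
        local_right = list(combinations(RIGHT_HUB, 2))
    else:
        raise ValueError(f"unknown local_mode {local_mode!r}")
    return {
        "global": ScaleDef.from_pairs("global", global_pairs, order),
        "large": ScaleDef.from_pairs("large", large, order),
        "local_left": ScaleDef.from_pairs("local_left", local_left, order),
        "local_right": ScaleDef.from_pairs("local_right", local_right, order),
    }


def scale_average(plv_table: pd.DataFrame, scale: ScaleDef) -> pd.DataFrame:
    """Unweighted mean PLV over the scale's pairs, per
    (subject_id, condition, window, band).

    Raises if any pair of the scale is absent from the table.
    """
    tagged = plv_table.set_index(["channel_i", "channel_j"]).sort_index()
    missing = [p for p in scale.pairs if p not in tagged.index]
    if missing:
        raise ValueError(f"scale {scale.name}: pairs missing from PLV table: "
                         f"{missing[:5]}")
    sub = tagged.loc[list(scale.pairs)].reset_index()
    out = (sub.groupby(["subject_id", "condition", "window", "band"],
                       dropna=False, sort=True)["plv"]
           .mean().reset_index().rename(columns={"plv": "mean_plv"}))
    out.insert(4, "scale", scale.name)
    return out


def all_scale_averages(plv_table: pd.DataFrame, scales: dict | None = None,
                       local_mode: str = "star") -> pd.DataFrame:
    """scale_average over every scale, concatenated."""
    if scales is None:
        scales = default_scales(local_mode=local_mode)
    return pd.concat([scale_average(plv_table, s) for s in scales.values()],
                     ignore_index=True)
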