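"""Readers and writers: interaction-matrix CSV, packaged field-study tables,
simulator configuration files, and run manifests.

Matrix format: plain CSV, first row and first column carry the individual
ids (sex encoded by an ``m``/``f`` prefix, e.g. ``m1``, ``f3``), cell
``[i, j]`` the number of decided fights ``i`` won over ``j``.  Files are
conventionally named after the composition label (``5m4f.csv``).
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .core import InteractionMatrix, sex_from_id
from .domworld import SimParams

__all__ = [
    "read_interaction_matrix",
    "write_interaction_matrix",
    "load_group_compositions",
    "load_dominance_table",
    "read_sim_config",
    "write_sim_config",
    "write_manifest",
]


def write_interaction_matrix(m: InteractionMatrix, path) -> None:
    df = pd.DataFrame(m.counts, index=m.ids, columns=m.ids)
    df.to_csv(path)


def read_interaction_matrix(path) -> InteractionMatrix:
    df = pd.read_csv(path, index_col=0)
    row_ids = [str(i) for i in df.index]
    col_ids = [str(c) for c in df.columns]
    if len(row_ids) != len(col_ids):
        raise ValueError(f"{path}: matrix is not square ({len(row_ids)}x{len(col_ids)})")
    for r, c in zip(row_ids, col_ids):
        if r != c:
            raise ValueError(f"{path}: row id {r!r} does not match column id {c!r}")
    vals = df.to_numpy()
    bad = np.argwhere(~np.isfinite(vals.astype(float)) | (vals.astype(float) < 0))
    if bad.size:
        i, j = bad[0]
        raise ValueError(f"{path}: invalid cell [{row_ids[i]},{col_ids[j]}] = {vals[i, j]}")
    if not np.all(vals == np.round(vals.astype(float))):
        frac = np.argwhere(vals != np.round(vals.astype(float)))[0]
        raise ValueError(
            f"{path}: non-integer cell [{row_ids[frac[0]]},{col_ids[frac[1]]}]"
        )
    sexes = [sex_from_id(i) for i in row_ids]
    return InteractionMatrix(ids=row_ids, sexes=sexes, counts=vals.astype(np.int64))


def _packaged(name: str) -> pd.DataFrame:
    with resources.files("domhier.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_group_compositions() -> pd.DataFrame:
    """The 14 analysed group-periods: site, group, composition, hours."""
    df = _packaged("table2.csv")
    if len(df) != 14:
        raise ValueError(f"composition fixture must have 14 rows, got {len(df)}")
    df["n_adults"] = df["n_males"] + df["n_females"]
    df["prop_males"] = df["n_males"] / df["n_adults"]
    return df


def load_dominance_table() -> pd.DataFrame:
    """Per group-period demography and dominance statistics (14 rows).

    Adds derived columns (``n_females``, recomputed proportion of males) and
    validates internal consistency of the packaged values.
    """
    df = _packaged("table3.csv")
    required = {
        "site", "group", "period", "prop_males", "n_adults", "n_males",
        "fdi", "mm_ago", "fm_ago", "n_aggressive", "pct_unknown",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"dominance fixture missing columns: {sorted(missing)}")
    if len(df) != 14:
        raise ValueError(f"dominance fixture must have 14 rows, got {len(df)}")
    df["n_females"] = df["n_adults"] - df["n_males"]
    recomputed = df["n_males"] / df["n_adults"]
    if np.any(np.abs(recomputed - df["prop_males"]) > 0.0051):
        raise ValueError("prop_males inconsistent with male/adult counts")
    # the published column is rounded to 2 decimals; models use the exact ratio
    df["prop_males_exact"] = recomputed
    df["group_period"] = (
        df["site"] + "/" + df["group"] + "/" + df["period"].astype(str)
    )
    return df


_PER_SEX_KEYS = {
    "InitialDominance": "initial_dominance",
    "StepDom": "step_dom",
}
_SCALAR_KEYS = {
    "NumberOfMentalBattles": ("num_mental_battles", int),
    "FieldOfView": ("field_of_view", float),
    "PersSpace": ("pers_space", float),
    "NearView": ("near_view", float),
    "MaxView": ("max_view", float),
    "FleeDist": ("flee_dist", float),
    "WithdrawDist": ("withdraw_dist", float),
    "ChaseDist": ("chase_dist", float),
    "MoveDist": ("move_dist", float),
    "WiggleTurn": ("wiggle_turn", float),
    "WiggleTurnError": ("wiggle_turn_error", float),
    "SearchTurn": ("search_turn", float),
    "SearchTurnError": ("search_turn_error", float),
    "WonTurn": ("won_turn", float),
    "WonTurnError": ("won_turn_error", float),
    "FleeTurn": ("flee_turn", float),
    "FleeTurnError": ("flee_turn_error", float),
    "worldSize": ("world_size", float),
    "startRadius": ("start_radius", float),
    "nPeriods": ("n_periods", int),
    "burnInPeriods": ("burn_in_periods", int),
    "stepDomConvention": ("step_dom_convention", str),
    "dominanceFloor": ("dominance_floor", float),
}


def write_sim_config(params: SimParams, path) -> None:
    """Flat ``key = value`` simulator configuration file."""
    lines = []
    for key, attr in _PER_SEX_KEYS.items():
        d = getattr(params, attr)
        lines.append(f"{key}.female = {d['female']}")
        lines.append(f"{key}.male = {d['male']}")
    for key, (attr, _) in _SCALAR_KEYS.items():
        lines.append(f"{key} = {getattr(params, attr)}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_sim_config(path) -> SimParams:
    params = SimParams()
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, value = (s.strip() for s in line.split("=", 1))
        if "." in key:
            base, sex = key.split(".", 1)
            sex = {"female": "female", "male": "male"}.get(sex)
            if base not in _PER_SEX_KEYS or sex is None:
                raise ValueError(f"{path}:{lineno}: unknown per-sex key {key!r}")
            getattr(params, _PER_SEX_KEYS[base])[sex] = float(value)
        elif key in _SCALAR_KEYS:
            attr, conv = _SCALAR_KEYS[key]
            setattr(params, attr, conv(value))
        elif key == "seed":
            pass  # seeds travel in the manifest, not the parameter set
        else:
            raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
    params.validate()
    return params


def write_manifest(path, *, seed, params: SimParams | None = None, **extra) -> None:
    """Write a JSON run manifest: config snapshot, seed, package version."""
    from . import __version__

    payload = {
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "package_version": __version__,
        "seed": seed,
    }
    if params is not None:
        payload["params"] = dataclasses.asdict(params)
    payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
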