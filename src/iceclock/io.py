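"""Readers/writers for gridded fields (CSV/NetCDF), segments and profiles (TSV)."""

from __future__ import annotations

import pandas as pd

from .flowline import FlowlineSegment, ScalarField, VelocityField

SEGMENT_COLUMNS = [
    "i",
    "length",
    "x_mid",
    "y_mid",
    "speed",
    "dt",
    "ab",
    "sigma",
    "ezz",
]


def _pivot_grid(df: pd.DataFrame, col: str) -> tuple:
    pivot = df.pivot(index="y", columns="x", values=col)
    if pivot.isna().any().any():
        raise ValueError(f"grid column {col!r} has missing nodes (incomplete grid)")
    return pivot.index.to_numpy(), pivot.columns.to_numpy(), pivot.to_numpy()


def read_velocity_csv(path) -> VelocityField:
    """Long-format CSV with columns x, y, u, v (one row per grid node)."""
    df = pd.read_csv(path)
    y, x, u = _pivot_grid(df, "u")
    _, _, v = _pivot_grid(df, "v")
    return VelocityField(x=x, y=y, u=u, v=v)


def read_scalar_csv(path) -> ScalarField:
    """Long-format CSV with columns x, y, ab, sigma (one row per grid node)."""
    df = pd.read_csv(path)
    y, x, values = _pivot_grid(df, "ab")
    _, _, sigma = _pivot_grid(df, "sigma")
    return ScalarField(x=x, y=y, values=values, sigma=sigma)


def read_velocity_netcdf(path, x="x", y="y", u="u", v="v") -> VelocityField:
    """NetCDF velocity grid with named coordinate/component variables."""
    import xarray as xr  # optional dependency path

    ds = xr.open_dataset(path)
    return VelocityField(
        x=ds[x].to_numpy(),
        y=ds[y].to_numpy(),
        u=ds[u].to_numpy(),
        v=ds[v].to_numpy(),
    )


def read_scalar_netcdf(path, x="x", y="y", values="ab", sigma="sigma") -> ScalarField:
    import xarray as xr

    ds = xr.open_dataset(path)
    return ScalarField(
        x=ds[x].to_numpy(),
        y=ds[y].to_numpy(),
        values=ds[values].to_numpy(),
        sigma=ds[sigma].to_numpy(),
    )


def write_segments_tsv(segments, path) -> None:
    """One row per flowline segment, columns as in SEGMENT_COLUMNS."""
    rows = [
        {
            "i": s.index,
            "length": s.length,
            "x_mid": s.midpoint[0],
            "y_mid": s.midpoint[1],
            "speed": s.speed,
            "dt": s.duration,
            "ab": s.basal_rate,
            "sigma": s.basal_rate_sigma,
            "ezz": s.strain_rate,
        }
        for s in segments
    ]
    pd.DataFrame(rows, columns=SEGMENT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_segments_tsv(path) -> list:
    df = pd.read_csv(path, sep="\t")
    missing = set(SEGMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"segments file missing columns: {sorted(missing)}")
    return [
        FlowlineSegment(
            index=int(r.i),
            length=float(r.length),
            midpoint=(float(r.x_mid), float(r.y_mid)),
            speed=float(r.speed),
            duration=float(r.dt),
            basal_rate=float(r.ab),
            basal_rate_sigma=float(r.sigma),
            strain_rate=float(r.ezz),
        )
        for r in df.itertuples()
    ]


def write_profile_tsv(profile, path) -> None:
    """Age-depth profile as TSV: depth_m, age_yr[, age_lo, age_hi]."""
    data = {"depth_m": profile.depth, "age_yr": profile.age}
    if profile.age_lo is not None:
        data["age_lo"] = profile.age_lo
    if profile.age_hi is not None:
        data["age_hi"] = profile.age_hi
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)
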