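"""Domain containers and plain-text I/O for spectra and kinetic traces.

All energies are in eV and all pump-probe delays in picoseconds; unit
conversions happen at the boundary (readers/CLI), never inside the analysis.

Files are tab-separated numeric columns with an optional ``#``-prefixed
header carrying ``key: value`` metadata (channel, laser_state, delay_ps).
CSV is accepted through the ``dialect`` flag. No smoothing or filtering is
ever applied during I/O: the downstream observable is a line width, and any
smoothing would bias it.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

CHANNELS = ("kalpha", "kbeta", "xanes")
LASER_STATES = ("on", "off", "n/a")


def _as_float_array(x) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"expected a 1-D array, got shape {arr.shape}")
    return arr


def _check_strictly_increasing(x: np.ndarray, name: str) -> None:
    bad = np.nonzero(np.diff(x) <= 0)[0]
    if bad.size:
        rows = ", ".join(str(i) for i in bad[:10])
        raise ValueError(
            f"{name} must be strictly increasing; "
            f"violations at row indices [{rows}]"
            + ("..." if bad.size > 10 else "")
        )


@dataclass(frozen=True)
class EnergySpectrum:
    """One emission or absorption spectrum on an ascending energy grid.

    Parameters
    ----------
    energy_ev : array
        Photon energy grid (eV), strictly ascending.
    intensity : array
        Signal per energy point (arbitrary counts).
    sigma : array, optional
        Per-point 1-sigma uncertainty, same units as ``intensity``,
        strictly positive where present.
    channel : {"kalpha", "kbeta", "xanes"}
    laser_state : {"on", "off", "n/a"}
    delay_ps : float, optional
        Pump-probe delay; absent for steady-state spectra.
    """

    energy_ev: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray | None = None
    channel: str = "kalpha"
    laser_state: str = "n/a"
    delay_ps: float | None = None

    def __post_init__(self):
        e = _as_float_array(self.energy_ev)
        i = _as_float_array(self.intensity)
        _check_strictly_increasing(e, "energy_ev")
        if i.shape != e.shape:
            raise ValueError("intensity and energy_ev must have equal length")
        s = self.sigma
        if s is not None:
            s = _as_float_array(s)
            if s.shape != e.shape:
                raise ValueError("sigma and energy_ev must have equal length")
            if np.any(s <= 0):
                raise ValueError("sigma must be strictly positive")
        if self.channel not in CHANNELS:
            raise ValueError(f"channel must be one of {CHANNELS}")
        if self.laser_state not in LASER_STATES:
            raise ValueError(f"laser_state must be one of {LASER_STATES}")
        object.__setattr__(self, "energy_ev", e)
        object.__setattr__(self, "intensity", i)
        object.__setattr__(self, "sigma", s)
        if self.delay_ps is not None:
            object.__setattr__(self, "delay_ps", float(self.delay_ps))

    def __len__(self) -> int:
        return self.energy_ev.size


@dataclass(frozen=True)
class TransientSpectrum:
    """Laser-on minus laser-off difference spectrum at one delay."""

    energy_ev: np.ndarray
    delta: np.ndarray
    sigma: np.ndarray | None = None
    delay_ps: float | None = None
    channel: str = "kalpha"
    normalized: bool = False

    def __post_init__(self):
        e = _as_float_array(self.energy_ev)
        d = _as_float_array(self.delta)
        _check_strictly_increasing(e, "energy_ev")
        if d.shape != e.shape:
            raise ValueError("delta and energy_ev must have equal length")
        s = self.sigma
        if s is not None:
            s = _as_float_array(s)
            if s.shape != e.shape:
                raise ValueError("sigma and energy_ev must have equal length")
        if self.channel not in CHANNELS:
            raise ValueError(f"channel must be one of {CHANNELS}")
        if self.normalized and abs(np.max(np.abs(d)) - 1.0) > 1e-12:
            raise ValueError("normalized transient must have max |delta| == 1")
        object.__setattr__(self, "energy_ev", e)
        object.__setattr__(self, "delta", d)
        object.__setattr__(self, "sigma", s)
        if self.delay_ps is not None:
            object.__setattr__(self, "delay_ps", float(self.delay_ps))

    def __len__(self) -> int:
        return self.energy_ev.size


@dataclass(frozen=True)
class KineticTrace:
    """Scalar observable versus pump-probe delay."""

    delay_ps: np.ndarray
    signal: np.ndarray
    sigma: np.ndarray | None = None
    label: str = ""

    def __post_init__(self):
        t = _as_float_array(self.delay_ps)
        y = _as_float_array(self.signal)
        _check_strictly_increasing(t, "delay_ps")
        if y.shape != t.shape:
            raise ValueError("signal and delay_ps must have equal length")
        s = self.sigma
        if s is not None:
            s = _as_float_array(s)
            if s.shape != t.shape:
                raise ValueError("sigma and delay_ps must have equal length")
            if np.any(s <= 0):
                raise ValueError("sigma must be strictly positive")
        object.__setattr__(self, "delay_ps", t)
        object.__setattr__(self, "signal", y)
        object.__setattr__(self, "sigma", s)

    def __len__(self) -> int:
        return self.delay_ps.size


# ---------------------------------------------------------------------------
# File I/O

_FMT = "%.17g"  # round-trips IEEE doubles exactly


def _delimiter(dialect: str) -> str | None:
    if dialect == "tsv":
        return None  # any whitespace on read; '\t' on write
    if dialect == "csv":
        return ","
    raise ValueError("dialect must be 'tsv' or 'csv'")


def _parse_header(path) -> dict:
    meta: dict = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, val = body.partition(":")
                meta[key.strip()] = val.strip()
    return meta


def _load_columns(path, dialect: str, min_cols: int) -> np.ndarray:
    delim = _delimiter(dialect)
    try:
        data = np.loadtxt(path, comments="#", delimiter=delim, ndmin=2)
    except ValueError as exc:
        raise ValueError(f"could not parse numeric columns from {path}: {exc}")
    if data.shape[1] < min_cols:
        raise ValueError(
            f"{path}: expected at least {min_cols} numeric columns, "
            f"found {data.shape[1]}"
        )
    return data


def read_spectrum(path, dialect: str = "tsv", **defaults) -> EnergySpectrum:
    """Read an :class:`EnergySpectrum` from a columnar text file.

    Header lines like ``# channel: kalpha`` set metadata; keyword
    ``defaults`` fill in anything the header omits.
    """
    data = _load_columns(path, dialect, 2)
    meta = _parse_header(path)
    kwargs = dict(defaults)
    if "channel" in meta:
        kwargs["channel"] = meta["channel"]
    if "laser_state" in meta:
        kwargs["laser_state"] = meta["laser_state"]
    if "delay_ps" in meta:
        kwargs["delay_ps"] = float(meta["delay_ps"])
    sigma = data[:, 2] if data.shape[1] >= 3 else None
    return EnergySpectrum(data[:, 0], data[:, 1], sigma=sigma, **kwargs)


def write_spectrum(spectrum: EnergySpectrum, path, dialect: str = "tsv") -> None:
    """Write a spectrum as ``energy  intensity [sigma]`` with a metadata header."""
    sep = "\t" if dialect == "tsv" else ","
    cols = [spectrum.energy_ev, spectrum.intensity]
    names = ["energy_ev", "intensity"]
    if spectrum.sigma is not None:
        cols.append(spectrum.sigma)
        names.append("sigma")
    header = [f"# channel: {spectrum.channel}",
              f"# laser_state: {spectrum.laser_state}"]
    if spectrum.delay_ps is not None:
        header.append(f"# delay_ps: {_FMT % spectrum.delay_ps}")
    header.append("# columns: " + sep.join(names))
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        np.savetxt(fh, np.column_stack(cols), fmt=_FMT, delimiter=sep)


def read_trace(path, dialect: str = "tsv", **defaults) -> KineticTrace:
    """Read a :class:`KineticTrace` (``delay_ps  signal [sigma]``) from file."""
    data = _load_columns(path, dialect, 2)
    meta = _parse_header(path)
    label = meta.get("label", defaults.get("label", ""))
    sigma = data[:, 2] if data.shape[1] >= 3 else None
    return KineticTrace(data[:, 0], data[:, 1], sigma=sigma, label=label)


def write_trace(trace: KineticTrace, path, dialect: str = "tsv") -> None:
    sep = "\t" if dialect == "tsv" else ","
    cols = [trace.delay_ps, trace.signal]
    names = ["delay_ps", "signal"]
    if trace.sigma is not None:
        cols.append(trace.sigma)
        names.append("sigma")
    header = [f"# label: {trace.label}", "# columns: " + sep.join(names)]
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        np.savetxt(fh, np.column_stack(cols), fmt=_FMT, delimiter=sep)


def resample(spectrum: EnergySpectrum, grid) -> EnergySpectrum:
    """Linearly interpolate a spectrum onto ``grid`` (no extrapolation).

    The target grid must lie inside the source range; interpolation is
    strictly linear so affine intensity profiles are reproduced exactly.
    """
    grid = _as_float_array(grid)
    _check_strictly_increasing(grid, "target grid")
    e = spectrum.energy_ev
    if grid[0] < e[0] or grid[-1] > e[-1]:
        raise ValueError(
            f"target grid [{grid[0]}, {grid[-1]}] extends outside the "
            f"source range [{e[0]}, {e[-1]}]; extrapolation is not allowed"
        )
    intensity = np.interp(grid, e, spectrum.intensity)
    sigma = None if spectrum.sigma is None else np.interp(grid, e, spectrum.sigma)
    return replace(spectrum, energy_ev=grid, intensity=intensity, sigma=sigma)
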