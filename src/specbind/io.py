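"""Delimited-text readers and writers for the data objects.

Files are plain text with a mandatory header row, ``#`` comment lines, and
comma, tab or whitespace delimiters (sniffed).  Temperatures are Celsius on
disk and kelvin in memory; concentrations are molar on both sides.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import SignalKind, TitrationSeries
from .kinetics import KineticTrace
from .melt import MeltTrace
from .quenching import DEFAULT_TAU0, QuenchSeries


def _read_table(path, required_columns) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=None, engine="python", comment="#")
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ValueError(f"cannot read {path}: {exc}") from exc
    missing = [c for c in required_columns if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing column(s) {missing}; expected columns {list(required_columns)}"
        )
    return df


def read_titration(
    path,
    protein_total: float,
    temperature: float,
    signal_kind: SignalKind = SignalKind.ABSORBANCE,
) -> TitrationSeries:
    """Read columns ``ligand_total_M, signal``; metadata comes as arguments."""
    df = _read_table(path, ("ligand_total_M", "signal"))
    return TitrationSeries(
        protein_total=protein_total,
        ligand_total=tuple(df["ligand_total_M"].astype(float)),
        signal=tuple(df["signal"].astype(float)),
        temperature=temperature,
        signal_kind=signal_kind,
    )


def write_titration(path, series: TitrationSeries) -> None:
    header = (
        f"# titration: protein_total_M={series.protein_total!r} "
        f"temperature_K={series.temperature!r} signal_kind={series.signal_kind.value}\n"
    )
    df = pd.DataFrame({"ligand_total_M": series.ligand_total, "signal": series.signal})
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def read_quench(path, F0: float = None, tau0: float = DEFAULT_TAU0) -> QuenchSeries:
    """Read columns ``Q_M, F``; F0 defaults to the reading at Q = 0."""
    df = _read_table(path, ("Q_M", "F"))
    return QuenchSeries.from_arrays(
        Q=df["Q_M"].astype(float), F=df["F"].astype(float), F0=F0, tau0=tau0
    )


def write_quench(path, series: QuenchSeries) -> None:
    header = f"# quench titration: F0={series.F0!r} tau0_s={series.tau0!r}\n"
    df = pd.DataFrame({"Q_M": series.Q, "F": series.F})
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def read_melt(path, label: str = "") -> MeltTrace:
    """Read columns ``temperature_C, signal`` (converted to kelvin)."""
    df = _read_table(path, ("temperature_C", "signal"))
    return MeltTrace.from_celsius(
        temperature_C=tuple(df["temperature_C"].astype(float)),
        signal=tuple(df["signal"].astype(float)),
        label=label or Path(path).stem,
    )


def write_melt(path, trace: MeltTrace) -> None:
    header = f"# melt trace: label={trace.label!r}\n"
    df = pd.DataFrame(
        {
            "temperature_C": [t - 273.15 for t in trace.temperature],
            "signal": trace.signal,
        }
    )
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def read_kinetic(path, A0: float = None, A_inf: float = None) -> KineticTrace:
    """Read columns ``time_s, signal``.

    ``A0`` defaults to the first reading and ``A_inf`` to the mean of the
    final 5% of the trace.
    """
    df = _read_table(path, ("time_s", "signal"))
    time = tuple(df["time_s"].astype(float))
    signal = tuple(df["signal"].astype(float))
    if A_inf is None:
        return KineticTrace.with_estimated_endpoint(time, signal, A0=A0)
    return KineticTrace(
        time=time,
        signal=signal,
        A0=float(signal[0]) if A0 is None else float(A0),
        A_inf=float(A_inf),
    )


def write_kinetic(path, trace: KineticTrace) -> None:
    header = f"# kinetic trace: A0={trace.A0!r} A_inf={trace.A_inf!r}\n"
    df = pd.DataFrame({"time_s": trace.time, "signal": trace.signal})
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")
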