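"""Delimited-text readers and writers for all pipeline inputs.

Formats are deliberately plain: spectral series as a matrix with a
wavelength first column and a condition header row; kinetic traces as
two columns with ``#key=value`` metadata lines; relaxation tables as
CSV with unit auto-detection from the header; SAXS profiles as 3-column
``.dat`` with comment tolerance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .equilibrium import SpectralSeries
from .kinetics import ChevronDataset, KineticTrace
from .relaxation import RelaxationRecord
from .saxs import SAXSProfile


# ---------------------------------------------------------------- series


def write_series(path, series: SpectralSeries) -> None:
    with open(path, "w") as fh:
        fh.write(f"# kind={series.kind}\n")
        fh.write("wavelength\t" + "\t".join(f"{c:g}" for c in series.axis2) + "\n")
        for wl, row in zip(series.axis1, series.matrix):
            fh.write(f"{wl:g}\t" + "\t".join(f"{x:.8g}" for x in row) + "\n")


def read_series(path) -> SpectralSeries:
    kind = "fluorescence"
    with open(path) as fh:
        lines = fh.readlines()
    rows = []
    header = None
    for line in lines:
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "kind=" in line:
                kind = line.split("kind=")[1].strip()
            continue
        if header is None:
            header = line.split("\t")
            continue
        rows.append([float(x) for x in line.split("\t")])
    arr = np.array(rows)
    conditions = np.array([float(x) for x in header[1:]])
    return SpectralSeries(arr[:, 0], conditions, arr[:, 1:], kind=kind)  # type: ignore[arg-type]


# ---------------------------------------------------------------- traces


def write_trace(path, trace: KineticTrace) -> None:
    with open(path, "w") as fh:
        fh.write(f"#D_final={trace.D_final:g}\n")
        fh.write(f"#direction={trace.direction}\n")
        for t, s in zip(trace.t, trace.signal):
            fh.write(f"{t:.8g}\t{s:.8g}\n")


def read_trace(path) -> KineticTrace:
    D_final, direction = np.nan, "refolding"
    t, s = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("#D_final="):
                    D_final = float(line.split("=", 1)[1])
                elif line.startswith("#direction="):
                    direction = line.split("=", 1)[1].strip()
                continue
            a, b = line.split()[:2]
            t.append(float(a))
            s.append(float(b))
    return KineticTrace(np.array(t), np.array(s), D_final=D_final, direction=direction)  # type: ignore[arg-type]


# ---------------------------------------------------------------- chevron


def write_chevron(path, data: ChevronDataset) -> None:
    df = pd.DataFrame({"D_M": data.D, "k_obs_s": data.k_obs})
    if data.phase is not None:
        df["phase"] = data.phase
    if data.direction is not None:
        df["direction"] = data.direction
    df.to_csv(path, index=False)


def read_chevron(path) -> ChevronDataset:
    df = pd.read_csv(path)
    return ChevronDataset(
        D=df["D_M"].to_numpy(),
        k_obs=df["k_obs_s"].to_numpy(),
        phase=df["phase"].to_numpy() if "phase" in df else None,
        direction=df["direction"].to_numpy() if "direction" in df else None,
    )


# ---------------------------------------------------------------- relaxation


def write_relaxation(path, records: list[RelaxationRecord]) -> None:
    df = pd.DataFrame(
        {
            "residue": [r.residue for r in records],
            "R1": [r.R1 for r in records],
            "R2": [r.R2 for r in records],
            "NOE": [r.NOE for r in records],
            "R1_err": [r.R1_err for r in records],
            "R2_err": [r.R2_err for r in records],
            "NOE_err": [r.NOE_err for r in records],
        }
    )
    df.to_csv(path, index=False)


def read_relaxation(path) -> list[RelaxationRecord]:
    """Read a relaxation CSV; T1/T2 columns in ms are converted to rates."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}

    def rate(row, which: str) -> float:
        if which.lower() in cols:  # R1 / R2 in s^-1
            return float(row[cols[which.lower()]])
        tcol = f"t{which[1]}_ms"
        if tcol in cols:
            return 1.0 / (float(row[cols[tcol]]) * 1e-3)
        raise KeyError(f"no {which} or {tcol} column")

    out = []
    for _, row in df.iterrows():
        out.append(
            RelaxationRecord(
                residue=int(row[cols["residue"]]),
                R1=rate(row, "R1"),
                R2=rate(row, "R2"),
                NOE=float(row[cols["noe"]]),
                R1_err=float(row[cols["r1_err"]]) if "r1_err" in cols else np.nan,
                R2_err=float(row[cols["r2_err"]]) if "r2_err" in cols else np.nan,
                NOE_err=float(row[cols["noe_err"]]) if "noe_err" in cols else np.nan,
            )
        )
    return out


# ---------------------------------------------------------------- SAXS


def write_saxs(path, profile: SAXSProfile) -> None:
    with open(path, "w") as fh:
        fh.write("# q_A^-1 I sigma\n")
        sig = profile.sigma if profile.sigma is not None else np.zeros_like(profile.q)
        for q, I, s in zip(profile.q, profile.I, sig):
            fh.write(f"{q:.8g} {I:.8g} {s:.8g}\n")


def read_saxs(path) -> SAXSProfile:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", ";", "%")):
                continue
            parts = line.replace(",", " ").split()
            try:
                vals = [float(p) for p in parts[:3]]
            except ValueError:
                continue  # header or unit line
            rows.append(vals + [0.0] * (3 - len(vals)))
    arr = np.array(rows)
    sigma = arr[:, 2] if np.any(arr[:, 2] > 0) else None
    return SAXSProfile(arr[:, 0], arr[:, 1], sigma)
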