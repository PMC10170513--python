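"""Plain-text interchange: COLVAR/HILLS-style files, configs, PDB export.

The columnar dialects follow the widely used convention of a leading
``#! FIELDS ...`` header naming the columns, whitespace-separated numeric
rows, and full-precision floats so that write→read round-trips exactly.

* COLVAR: ``#! FIELDS time cv1 cv2 ...`` — a CV time series.
* HILLS:  ``#! FIELDS time center_1..n sigma_1..n height biasf`` — the
  deposited Gaussians of a metadynamics run.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import yaml

from .engine import Hill, MetaDTrajectory

PathLike = Union[str, Path]

_FMT = "%.17g"  # round-trip-exact float formatting


def write_colvar(
    path: PathLike,
    times: np.ndarray,
    cvs: np.ndarray,
    names: Optional[Sequence[str]] = None,
    extra: Optional[dict] = None,
) -> None:
    """Write a CV time series; ``extra`` maps column name → array."""
    times = np.asarray(times, float)
    cvs = np.atleast_2d(np.asarray(cvs, float))
    if cvs.shape[0] != times.shape[0]:
        cvs = cvs.T
    names = list(names) if names else [f"cv{i + 1}" for i in range(cvs.shape[1])]
    cols = [times] + [cvs[:, i] for i in range(cvs.shape[1])]
    header = ["time"] + names
    for key, arr in (extra or {}).items():
        header.append(key)
        cols.append(np.asarray(arr, float))
    data = np.column_stack(cols)
    with open(path, "w") as fh:
        fh.write("#! FIELDS " + " ".join(header) + "\n")
        np.savetxt(fh, data, fmt=_FMT)


def read_colvar(path: PathLike) -> tuple[list[str], np.ndarray]:
    """Read a COLVAR-style file; returns (column names, data matrix)."""
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#!"):
            raise ValueError(f"{path}: missing '#! FIELDS' header")
        fields = first.split()[2:]
        data = np.loadtxt(fh, ndmin=2)
    if data.size and data.shape[1] != len(fields):
        raise ValueError(f"{path}: {len(fields)} fields but {data.shape[1]} columns")
    return fields, data


def write_hills(path: PathLike, hills: Sequence[Hill], bias_factor: float = 0.0) -> None:
    """Write deposited hills in the HILLS-style dialect.

    ``biasf`` records the well-tempered bias factor column; 0 denotes a
    non-well-tempered run.
    """
    n = len(hills[0].center) if hills else 1
    header = (
        ["time"]
        + [f"center_{i + 1}" for i in range(n)]
        + [f"sigma_{i + 1}" for i in range(n)]
        + ["height", "biasf"]
    )
    with open(path, "w") as fh:
        fh.write("#! FIELDS " + " ".join(header) + "\n")
        for h in hills:
            row = [h.deposit_time, *h.center, *h.widths, h.height, bias_factor]
            fh.write(" ".join(_FMT % v for v in row) + "\n")


def read_hills(path: PathLike) -> tuple[list[Hill], float]:
    """Read a HILLS-style file back into hill objects (+ bias factor)."""
    fields, data = read_colvar(path)
    n = sum(1 for f in fields if f.startswith("center_"))
    if n == 0 or fields[0] != "time" or "height" not in fields:
        raise ValueError(f"{path}: not a HILLS-style header: {fields}")
    hills = []
    biasf = 0.0
    for row in data:
        hills.append(
            Hill(
                center=tuple(row[1 : 1 + n]),
                widths=tuple(row[1 + n : 1 + 2 * n]),
                height=float(row[1 + 2 * n]),
                deposit_time=float(row[0]),
            )
        )
        biasf = float(row[2 + 2 * n])
    return hills, biasf


def write_trajectory(path: PathLike, traj: MetaDTrajectory) -> None:
    """Write a deposition record as COLVAR-style columns.

    Columns: time, the CVs, the pre-deposition bias, the deposited height
    and the unbound flag.
    """
    names = list(traj.cv_names) or [f"cv{i + 1}" for i in range(traj.n_cvs)]
    write_colvar(
        path,
        traj.times,
        traj.cvs,
        names=names,
        extra={
            "bias": traj.bias_before,
            "height": traj.heights,
            "unbound": traj.unbound.astype(float),
        },
    )


def read_trajectory(path: PathLike) -> MetaDTrajectory:
    """Read a deposition record written by :func:`write_trajectory`."""
    fields, data = read_colvar(path)
    required = {"time", "bias", "height", "unbound"}
    if not required.issubset(fields):
        raise ValueError(f"{path}: missing columns {required - set(fields)}")
    cv_names = [f for f in fields if f not in required]
    col = {f: data[:, i] for i, f in enumerate(fields)}
    unbound = col["unbound"] > 0.5
    return MetaDTrajectory(
        times=col["time"],
        cvs=np.column_stack([col[f] for f in cv_names])
        if cv_names
        else np.empty((len(data), 0)),
        bias_before=col["bias"],
        heights=col["height"],
        unbound=unbound,
        status="unbound" if unbound.any() else "max_time_reached",
        hills=[],
        cv_names=tuple(cv_names),
    )


def load_config(path: PathLike) -> dict:
    """Load a declarative YAML/JSON run configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return cfg


def save_config(path: PathLike, cfg: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def write_pdb(path: PathLike, coords: np.ndarray, names: Optional[Sequence[str]] = None) -> None:
    """Minimal PDB export of toy coordinates for visual inspection."""
    coords = np.asarray(coords, float)
    with open(path, "w") as fh:
        for i, xyz in enumerate(coords):
            name = (names[i] if names else "C")[:4]
            fh.write(
                f"HETATM{i + 1:>5} {name:<4} TOY A{1:>4}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00\n"
            )
        fh.write("END\n")
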