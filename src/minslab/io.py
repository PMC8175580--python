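"""File I/O: trajectories (HDF5/NPZ), movie stacks (TIFF + JSON sidecar),
steady states (JSON + NPZ), correlation reports (CSV + JSON)."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from .model import FieldState, SteadyState
from .params import Geometry, KineticParameters, Totals
from .patterns import CorrelationReport, MovieStack
from .simulate import Kymograph, Trajectory


def save_trajectory(path: str | Path, traj: Trajectory) -> None:
    """Write a trajectory to HDF5 (fields, membrane densities, grids, attrs)."""
    import h5py

    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["n_snapshots"] = len(traj.states)
        f.attrs["seed"] = -1 if traj.seed is None else traj.seed
        for k, v in traj.meta.items():
            f.attrs[f"meta_{k}"] = v
        g = traj.geom
        f.attrs["H"] = g.H
        f.attrs["dz"] = g.H / g.nz
        f.attrs["L_x"] = -1.0 if g.L_x is None else g.L_x
        f.attrs["membranes"] = g.membranes
        for name in ("k_D", "k_dD", "k_dE", "k_de", "lambda_exch", "D_b", "D_m"):
            f.attrs[name] = getattr(traj.params, name)
        f.attrs["n_D"] = traj.totals.n_D
        f.attrs["n_E"] = traj.totals.n_E
        f.create_dataset("times", data=traj.times)
        nt = len(traj.states)
        st0 = traj.states[0]
        for name in ("c_DD", "c_DT", "c_E"):
            arr = np.stack([getattr(s, name) for s in traj.states])
            f.create_dataset(name, data=arr, compression="gzip", compression_opts=1)
        for face in st0.membranes:
            for k in ("m_d", "m_de"):
                arr = np.stack([s.membranes[face][k] for s in traj.states])
                f.create_dataset(f"{face}_{k}", data=arr)


def load_trajectory(path: str | Path) -> Trajectory:
    import h5py

    with h5py.File(path, "r") as f:
        params = KineticParameters(
            **{k: float(f.attrs[k]) for k in
               ("k_D", "k_dD", "k_dE", "k_de", "lambda_exch", "D_b", "D_m")})
        totals = Totals(n_D=float(f.attrs["n_D"]), n_E=float(f.attrs["n_E"]))
        L_x = float(f.attrs["L_x"])
        geom = Geometry(
            H=float(f.attrs["H"]), dz=float(f.attrs["dz"]),
            L_x=None if L_x < 0 else L_x,
            dx=None if L_x < 0 else L_x / f["c_DD"].shape[1],
            membranes=str(f.attrs["membranes"]),
        )
        times = f["times"][:]
        faces = ["bottom"] + (["top"] if geom.membranes == "both_faces" else [])
        states = []
        for i in range(len(times)):
            membranes = {face: {"m_d": f[f"{face}_m_d"][i],
                                "m_de": f[f"{face}_m_de"][i]} for face in faces}
            states.append(FieldState(
                c_DD=f["c_DD"][i], c_DT=f["c_DT"][i], c_E=f["c_E"][i],
                membranes=membranes, time=float(times[i])))
        seed = int(f.attrs.get("seed", -1))
        meta = {k[5:]: f.attrs[k] for k in f.attrs if k.startswith("meta_")}
    return Trajectory(times=times, states=states, params=params, geom=geom,
                      totals=totals, seed=None if seed < 0 else seed, meta=meta)


def save_stack(path: str | Path, stack: MovieStack) -> None:
    """Multi-page TIFF plus a JSON sidecar with the calibration."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, stack.data.astype(np.float32), photometric="minisblack")
    sidecar = path.with_suffix(path.suffix + ".json")
    with open(sidecar, "w") as fh:
        json.dump({"pixel_size_um": stack.pixel_size,
                   "frame_interval_s": stack.frame_interval,
                   "plane": stack.plane, "channel": stack.channel}, fh, indent=2)


def load_stack(path: str | Path, pixel_size: float | None = None,
               frame_interval: float | None = None) -> MovieStack:
    """Read a TIFF stack; calibration from the sidecar unless given."""
    import tifffile

    path = Path(path)
    data = tifffile.imread(path)
    meta = {}
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = json.load(fh)
    px = pixel_size if pixel_size is not None else meta.get("pixel_size_um")
    dt = frame_interval if frame_interval is not None else meta.get("frame_interval_s")
    if px is None or dt is None:
        raise ValueError(f"no calibration for {path}: pass pixel_size and frame_interval")
    return MovieStack(data=np.asarray(data, dtype=float), pixel_size=px,
                      frame_interval=dt,
                      plane=meta.get("plane", "single"),
                      channel=meta.get("channel", ""))


def save_steady_state(prefix: str | Path, ss: SteadyState, n_z: int = 200) -> None:
    """Scalars to <prefix>.json, vertical profiles to <prefix>.npz."""
    prefix = Path(prefix)
    with open(prefix.with_suffix(".json"), "w") as fh:
        json.dump(ss.summary(), fh, indent=2)
    z = np.linspace(0, ss.geom.H, n_z)
    np.savez(prefix.with_suffix(".npz"), z=z,
             c_DD=ss.c_DD_profile(z), c_DT=ss.c_DT_profile(z),
             c_E=np.full_like(z, ss.c_E))


def save_correlation_report(prefix: str | Path, rep: CorrelationReport) -> None:
    """Per-cell CSV (cell_x, cell_y, corr) plus a JSON summary."""
    prefix = Path(prefix)
    rows = ["cell_x_um,cell_y_um,correlation"]
    for iy, cy in enumerate(rep.cell_centers_y):
        for ix, cx in enumerate(rep.cell_centers_x):
            v = rep.correlations[iy, ix]
            rows.append(f"{cx:.3f},{cy:.3f},{'' if np.isnan(v) else f'{v:.6f}'}")
    prefix.with_suffix(".csv").write_text("\n".join(rows) + "\n")
    counts, edges = rep.histogram
    with open(prefix.with_suffix(".json"), "w") as fh:
        json.dump({
            "cell_size_um": rep.cell_size,
            "thresholds": list(rep.thresholds),
            "fractions": rep.fractions,
            "n_undefined": rep.n_undefined,
            "histogram_counts": [int(c) for c in counts],
            "histogram_edges": [float(e) for e in edges],
        }, fh, indent=2)


def save_kymograph(prefix: str | Path, kymo: Kymograph, png: bool = False) -> None:
    """CSV/NPZ kymograph export with optional quick-look PNG."""
    prefix = Path(prefix)
    np.savez(prefix.with_suffix(".npz"), data=kymo.data, positions=kymo.positions,
             times=kymo.times, dx=kymo.dx, dt=kymo.dt)
    if png:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        ax.imshow(kymo.data, aspect="auto", origin="lower",
                  extent=[kymo.times[0], kymo.times[-1],
                          kymo.positions[0], kymo.positions[-1]], cmap="viridis")
        ax.set_xlabel("time (s)")
        ax.set_ylabel(f"position (μm) — {kymo.quantity}")
        fig.tight_layout()
        fig.savefig(prefix.with_suffix(".png"), dpi=120)
        plt.close(fig)
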