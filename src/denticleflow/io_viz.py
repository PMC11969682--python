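"""Readers/writers for profiles, masks, fields, configs, and figures.

Formats are deliberately plain: CSV polylines for profiles, legacy ASCII
VTK for fields (STRUCTURED_POINTS on uniform grids, RECTILINEAR_GRID on
graded ones), P5 PGM plus a JSON sidecar for masks, TOML for experiment
configs.  Everything round-trips losslessly at stored precision.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from shapely.geometry import Polygon

from . import __version__
from .geometry import DenticleProfile, MaskGrid
from .solver import FlowSolution, FluidProps

log = logging.getLogger(__name__)


class ProfileFormatError(ValueError):
    pass


# ---------------------------------------------------------------- profiles

def write_profile_csv(profile: DenticleProfile, path) -> None:
    """Two-column x_m,y_m CSV, one vertex per row, closed implicitly."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("x_m,y_m\n")
        for x, y in profile.vertices:
            fh.write(f"{float(x)!r},{float(y)!r}\n")
    log.info("profile written: %s (%d vertices)", path, len(profile.vertices))


def read_profile_csv(path, orientation: str = "rostral") -> DenticleProfile:
    path = Path(path)
    verts = []
    with path.open() as fh:
        header = fh.readline()
        if not header.lower().startswith("x_m"):
            raise ProfileFormatError(f"{path}:1: expected 'x_m,y_m' header")
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            try:
                if len(parts) != 2:
                    raise ValueError
                verts.append((float(parts[0]), float(parts[1])))
            except ValueError:
                raise ProfileFormatError(
                    f"{path}:{lineno}: malformed vertex row {line!r}") from None
    arr = np.array(verts, float)
    if len(arr) < 3:
        raise ProfileFormatError(f"{path}: fewer than 3 vertices")
    poly = Polygon(arr)
    if not (poly.is_simple and poly.is_valid):
        # name the first offending vertex for the error message
        for k in range(len(arr)):
            if not Polygon(np.delete(arr, k, axis=0)).is_valid:
                continue
            raise ProfileFormatError(
                f"{path}: polygon self-intersects near vertex {k} "
                f"({arr[k, 0]}, {arr[k, 1]})")
        raise ProfileFormatError(f"{path}: polygon is not simple")
    if abs(float(arr[:, 1].min())) > 1e-12:
        raise ProfileFormatError(
            f"{path}: profile min y = {arr[:, 1].min()}, must be 0 "
            "(baseline on the domain floor)")
    L = float(arr[:, 0].max() - arr[:, 0].min())
    return DenticleProfile(vertices=arr, model_length_L=L,
                           orientation=orientation,
                           provenance="user_supplied")


# ------------------------------------------------------------------- masks

def write_mask_pgm(mask: MaskGrid, path) -> None:
    """Binary PGM (P5), solid=255, plus a JSON sidecar with the grid."""
    path = Path(path)
    img = (mask.solid.T[::-1] * 255).astype(np.uint8)   # row 0 at the top
    with path.open("wb") as fh:
        fh.write(f"P5\n{mask.nx} {mask.ny}\n255\n".encode())
        fh.write(img.tobytes())
    sidecar = {"spacing_h": mask.spacing_h, "origin_x": mask.origin[0],
               "origin_y": mask.origin[1], "nx": mask.nx, "ny": mask.ny,
               "dx": mask.dx.tolist(), "dy": mask.dy.tolist()}
    Path(str(path) + ".json").write_text(json.dumps(sidecar))


def read_mask_pgm(path) -> MaskGrid:
    path = Path(path)
    with path.open("rb") as fh:
        magic = fh.readline().strip()
        if magic != b"P5":
            raise ValueError(f"{path}: not a P5 PGM")
        dims = fh.readline().split()
        nx, ny = int(dims[0]), int(dims[1])
        fh.readline()                                   # maxval
        img = np.frombuffer(fh.read(nx * ny), np.uint8).reshape(ny, nx)
    side = json.loads(Path(str(path) + ".json").read_text())
    solid = (img[::-1].T > 127)
    return MaskGrid(spacing_h=side["spacing_h"], nx=nx, ny=ny, solid=solid,
                    origin=(side["origin_x"], side["origin_y"]),
                    dx=np.array(side["dx"]), dy=np.array(side["dy"]))


# ------------------------------------------------------------------ fields

def write_fields_vtk(solution: FlowSolution, path, extra: dict | None = None
                     ) -> None:
    """Legacy ASCII VTK with cell-centered u, v, p, vorticity, mask as
    POINT_DATA on the cell-center lattice."""
    from .postprocess import vorticity
    path = Path(path)
    nx, ny = len(solution.xc), len(solution.yc)
    uniform = (np.allclose(solution.dx, solution.dx[0])
               and np.allclose(solution.dy, solution.dy[0]))
    om = vorticity(solution)
    om = np.where(np.isnan(om), 0.0, om)
    fields = {"u": solution.u, "v": solution.v, "p": solution.p,
              "vorticity": om, "mask": solution.solid.astype(float)}
    if extra:
        fields.update(extra)
    with path.open("w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"denticleflow fields (converged={solution.converged})\n")
        fh.write("ASCII\n")
        if uniform:
            fh.write("DATASET STRUCTURED_POINTS\n")
            fh.write(f"DIMENSIONS {nx} {ny} 1\n")
            fh.write(f"ORIGIN {float(solution.xc[0])!r} "
                     f"{float(solution.yc[0])!r} 0\n")
            fh.write(f"SPACING {float(solution.dx[0])!r} "
                     f"{float(solution.dy[0])!r} 1\n")
        else:
            fh.write("DATASET RECTILINEAR_GRID\n")
            fh.write(f"DIMENSIONS {nx} {ny} 1\n")
            fh.write(f"X_COORDINATES {nx} double\n")
            fh.write(" ".join(repr(float(x)) for x in solution.xc) + "\n")
            fh.write(f"Y_COORDINATES {ny} double\n")
            fh.write(" ".join(repr(float(y)) for y in solution.yc) + "\n")
            fh.write("Z_COORDINATES 1 double\n0\n")
        fh.write(f"POINT_DATA {nx * ny}\n")
        for name, data in fields.items():
            fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            # VTK orders x fastest
            flat = np.asarray(data, float).T.ravel()
            fh.write("\n".join(repr(float(val)) for val in flat) + "\n")
    log.info("fields written: %s (%dx%d)", path, nx, ny)


def read_fields_vtk(path) -> dict:
    """Parse the files written by :func:`write_fields_vtk` back into a dict
    of arrays plus the coordinate vectors."""
    path = Path(path)
    tokens = path.read_text().split("\n")
    it = iter(tokens)
    out: dict = {}
    nx = ny = None
    for line in it:
        parts = line.split()
        if not parts:
            continue
        if parts[0] == "DIMENSIONS":
            nx, ny = int(parts[1]), int(parts[2])
        elif parts[0] == "ORIGIN":
            out["origin"] = (float(parts[1]), float(parts[2]))
        elif parts[0] == "SPACING":
            out["spacing"] = (float(parts[1]), float(parts[2]))
        elif parts[0] in ("X_COORDINATES", "Y_COORDINATES"):
            n = int(parts[1])
            vals: list[float] = []
            while len(vals) < n:
                vals.extend(float(v) for v in next(it).split())
            out["xc" if parts[0][0] == "X" else "yc"] = np.array(vals)
        elif parts[0] == "SCALARS":
            name = parts[1]
            next(it)                                    # LOOKUP_TABLE
            vals = []
            while len(vals) < nx * ny:
                vals.extend(float(v) for v in next(it).split())
            out[name] = np.array(vals).reshape(ny, nx).T
    if "spacing" in out and "xc" not in out:
        ox, oy = out["origin"]
        sx, sy = out["spacing"]
        out["xc"] = ox + sx * np.arange(nx)
        out["yc"] = oy + sy * np.arange(ny)
    return out


# ---------------------------------------------------------------- manifest

@dataclass
class RunManifest:
    run_id: str
    config: dict
    seeds: dict
    files: list = field(default_factory=list)
    software_version: str = __version__
    timestamp: str = field(
        default_factory=lambda: datetime.datetime.now().isoformat(
            timespec="seconds"))

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def read_experiment_config(path) -> dict:
    """TOML experiment file: a [defaults] table plus [[runs]] entries."""
    with open(path, "rb") as fh:
        return tomllib.load(fh)


# ----------------------------------------------------------------- figures

def render_panel(solution: FlowSolution, path, style: str = "velocity",
                 n_seeds: int = 40, x_window: tuple | None = None,
                 dpi: int = 150) -> None:
    """Streamlines colored by velocity or vorticity magnitude over the
    filled solid geometry, with a scale bar.  Presentational only."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from .postprocess import streamlines, vorticity

    xc, yc = solution.xc, solution.yc
    if x_window is None:
        cols = solution.solid.any(axis=1)
        if cols.any():
            idx = np.flatnonzero(cols)
            pad = 2e-4
            x_window = (xc[idx[0]] - pad, xc[idx[-1]] + pad)
        else:
            x_window = (xc[0], xc[-1])
    ymax_solid = 0.0
    if solution.solid.any():
        ymax_solid = yc[np.nonzero(solution.solid.any(axis=0))[0][-1]]
    y_top = min(yc[-1], max(4e-4, 3 * ymax_solid))

    seeds = [(x_window[0] + 1e-6, y)
             for y in np.linspace(yc[1], y_top, n_seeds)]
    lines = streamlines(solution, seeds, max_length=1.5 * (x_window[1]
                                                           - x_window[0]))
    if style == "vorticity":
        om = vorticity(solution)
        fld = np.where(np.isnan(om), 0.0, np.abs(om))
        label = "|vorticity| (1/s)"
    else:
        fld = solution.speed
        label = "speed (m/s)"
    from scipy.interpolate import RegularGridInterpolator
    fi = RegularGridInterpolator((xc, yc), fld, bounds_error=False,
                                 fill_value=0.0)

    fig, ax = plt.subplots(figsize=(9, 3))
    vmax = np.percentile(fld[~solution.solid], 99.5)
    for ln in lines:
        if len(ln) < 2:
            continue
        vals = fi(ln)
        ax.scatter(ln[:, 0], ln[:, 1], c=vals, s=0.3, cmap="viridis",
                   vmin=0, vmax=vmax, rasterized=True)
    ax.pcolormesh(xc, yc, np.where(solution.solid, 1.0, np.nan).T,
                  cmap="gray_r", vmin=0, vmax=1.5)
    ax.plot([x_window[0] + 1e-4, x_window[0] + 2e-4], [y_top * 0.95] * 2,
            "k-", lw=2)
    ax.text(x_window[0] + 1e-4, y_top * 0.97, "100 um", fontsize=7)
    ax.set_xlim(*x_window)
    ax.set_ylim(0, y_top)
    ax.set_xlabel("x (m)")
    ax.set_ylabel("y (m)")
    sm = plt.cm.ScalarMappable(cmap="viridis",
                               norm=plt.Normalize(0, vmax))
    fig.colorbar(sm, ax=ax, label=label)
    fig.tight_layout()
    fig.savefig(path, dpi=dpi)
    plt.close(fig)
    log.info("panel written: %s (%s)", path, style)
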