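"""Readers/writers: raster images (MetaImage/NRRD), surfaces (legacy VTK /
CSV polyline), DG fields (legacy VTK + native HDF5) and YAML configuration.

All files use physical coordinates; images carry origin and spacing.  2D
contours are stored as ordered vertex lists, counterclockwise = inside on
the left.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

from .basis import DGBasis, DGVectorField
from .energy import RegistrationConfig
from .images import GridGeometry, RasterImage, Surface
from .mesh import Tessellation


# --------------------------------------------------------------------------
# raster images (SimpleITK: .mhd/.mha/.nrrd)
# --------------------------------------------------------------------------

def write_image(image: RasterImage, path) -> None:
    import SimpleITK as sitk

    # our arrays are x-fastest-varying logical order [x, y(, z)];
    # SimpleITK arrays are indexed [z, y, x]
    arr = np.ascontiguousarray(image.values.T)
    img = sitk.GetImageFromArray(arr)
    img.SetOrigin(tuple(float(o) for o in image.grid.origin))
    img.SetSpacing(tuple(float(s) for s in image.grid.spacing))
    sitk.WriteImage(img, str(path))


def read_image(path) -> RasterImage:
    import SimpleITK as sitk

    img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img).T
    grid = GridGeometry(tuple(img.GetOrigin()), tuple(img.GetSpacing()),
                        arr.shape)
    return RasterImage(grid, arr.astype(float))


# --------------------------------------------------------------------------
# surfaces
# --------------------------------------------------------------------------

def write_surface(surface: Surface, path) -> None:
    """CSV polyline for 2D contours, legacy-VTK polydata for 3D meshes."""
    path = Path(path)
    if surface.dim == 2:
        np.savetxt(path, surface.vertices, delimiter=",",
                   header="x,y", comments="")
        return
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\nfealign surface\nASCII\n")
        f.write("DATASET POLYDATA\n")
        f.write(f"POINTS {len(surface.vertices)} double\n")
        for v in surface.vertices:
            f.write(f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
        m = len(surface.cells)
        f.write(f"POLYGONS {m} {4 * m}\n")
        for c in surface.cells:
            f.write(f"3 {c[0]} {c[1]} {c[2]}\n")


def read_surface(path) -> Surface:
    path = Path(path)
    text = path.read_text()
    if text.lstrip().startswith("# vtk"):
        return _read_vtk_polydata(text)
    verts = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    if verts.shape[1] != 2:
        raise ValueError("CSV polyline must have exactly two columns")
    return Surface.closed_polyline(verts)


def _read_vtk_polydata(text: str) -> Surface:
    tokens = text.split()
    def find(kw):
        for i, t in enumerate(tokens):
            if t == kw:
                return i
        raise ValueError(f"missing {kw} section in VTK file")
    ip = find("POINTS")
    n = int(tokens[ip + 1])
    coords = np.array(tokens[ip + 3: ip + 3 + 3 * n], dtype=float)
    verts = coords.reshape(n, 3)
    ic = find("POLYGONS")
    m = int(tokens[ic + 1])
    cells = []
    pos = ic + 3
    for _ in range(m):
        k = int(tokens[pos])
        if k != 3:
            raise ValueError("only triangle polydata is supported")
        cells.append([int(tokens[pos + 1]), int(tokens[pos + 2]),
                      int(tokens[pos + 3])])
        pos += k + 1
    return Surface(verts, np.array(cells))


# --------------------------------------------------------------------------
# DG fields
# --------------------------------------------------------------------------

def save_field(field: DGVectorField, path) -> None:
    """Native HDF5 container: mesh + order + DOFs."""
    import h5py

    mesh = field.basis.mesh
    with h5py.File(path, "w") as f:
        f.attrs["order"] = field.basis.order
        g = f.create_group("mesh")
        g.create_dataset("origin", data=mesh.origin)
        g.create_dataset("size", data=mesh.size)
        g.create_dataset("levels", data=np.array([k[0] for k in mesh.leaves]))
        g.create_dataset("indices",
                         data=np.array([k[1] for k in mesh.leaves], dtype=int))
        f.create_dataset("dofs", data=field.dofs)


def load_field(path) -> DGVectorField:
    import h5py

    with h5py.File(path, "r") as f:
        order = int(f.attrs["order"])
        origin = f["mesh/origin"][...]
        size = f["mesh/size"][...]
        levels = f["mesh/levels"][...]
        indices = f["mesh/indices"][...]
        dofs = f["dofs"][...]
    leaves = [(int(l), tuple(int(i) for i in idx))
              for l, idx in zip(levels, indices)]
    basis = DGBasis(Tessellation(origin, size, leaves), order)
    return DGVectorField(basis, dofs)


def write_field_vtk(field: DGVectorField, path) -> None:
    """Legacy-VTK unstructured export (per-element corner vertices, so the
    discontinuous structure is preserved) for visualization."""
    mesh = field.basis.mesh
    dim = mesh.dim
    offsets = np.array(list(np.ndindex(*([2] * dim))), dtype=float)
    if dim == 2:
        corner_order = [0, 1, 3, 2]        # VTK_QUAD winding
        cell_type = 9
    else:
        corner_order = [0, 1, 3, 2, 4, 5, 7, 6]   # VTK_HEXAHEDRON
        cell_type = 12
    pts = []
    vecs = []
    cells = []
    for e in range(mesh.n_elements):
        corners = mesh.corners[e] + offsets * mesh.widths[e]
        vals = field(corners)
        start = len(pts)
        for o in corner_order:
            pts.append(corners[o])
            vecs.append(vals[o])
        cells.append(list(range(start, start + len(corner_order))))
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\nfealign field\nASCII\n")
        f.write("DATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {len(pts)} double\n")
        for p in pts:
            row = list(p) + [0.0] * (3 - dim)
            f.write(" ".join(f"{x:.17g}" for x in row) + "\n")
        f.write(f"CELLS {len(cells)} {sum(len(c) + 1 for c in cells)}\n")
        for c in cells:
            f.write(f"{len(c)} " + " ".join(str(i) for i in c) + "\n")
        f.write(f"CELL_TYPES {len(cells)}\n")
        for _ in cells:
            f.write(f"{cell_type}\n")
        f.write(f"POINT_DATA {len(pts)}\n")
        f.write("VECTORS displacement double\n")
        for v in vecs:
            row = list(v) + [0.0] * (3 - dim)
            f.write(" ".join(f"{x:.17g}" for x in row) + "\n")


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

_EXTRA_KEYS = {"grid_shape", "seed"}


def config_from_dict(data: dict) -> tuple[RegistrationConfig, dict]:
    """Build a config from a YAML-style dict; unknown keys are rejected."""
    known = {f.name for f in dataclasses.fields(RegistrationConfig)}
    cfg_kwargs = {}
    extras = {}
    for key, value in data.items():
        if key in known:
            if key == "theta" and value is not None:
                value = tuple(float(v) for v in value)
            cfg_kwargs[key] = value
        elif key in _EXTRA_KEYS:
            extras[key] = value
        else:
            raise ValueError(f"unknown configuration key {key!r}")
    return RegistrationConfig(**cfg_kwargs), extras


def config_to_dict(config: RegistrationConfig) -> dict:
    d = dataclasses.asdict(config)
    if d.get("theta") is not None:
        d["theta"] = list(d["theta"])
    return d


def read_config(path) -> tuple[RegistrationConfig, dict]:
    import yaml

    with open(path) as f:
        data = yaml.safe_load(f) or {}
    if not isinstance(data, dict):
        raise ValueError("configuration file must hold a mapping")
    return config_from_dict(data)


def write_config(config: RegistrationConfig, path, extras: dict | None = None) -> None:
    import yaml

    data = config_to_dict(config)
    if extras:
        data.update(extras)
    with open(path, "w") as f:
        yaml.safe_dump(data, f, sort_keys=True)
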