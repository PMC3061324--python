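"""Text file formats: .tri meshes, .geom/.cond models, ASCII matrices,
sensor and dipole description files.

All readers are strict: malformed counts, out-of-range indices and
non-finite values raise ``FileFormatError`` naming the offence.  All
writers round-trip bit-compatibly through their reader for the textual
fields.

Matrix format: a header line ``rows cols [symmetric]`` followed by
whitespace-separated values (full matrix row-major, or the lower triangle
row by row for symmetric matrices), written with repr-exact floats.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np

from .mesh import HeadModel, TriangleMesh, check_nesting

__all__ = [
    "FileFormatError",
    "read_tri",
    "write_tri",
    "read_geom",
    "read_cond",
    "read_head_model",
    "read_matrix",
    "write_matrix",
    "read_dipoles",
    "read_points",
    "read_meg_sensors",
]


class FileFormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# .tri (BrainVisa dialect)
# ---------------------------------------------------------------------------

def read_tri(path) -> TriangleMesh:
    """Read a .tri mesh: ``- N`` / N lines ``x y z nx ny nz`` /
    ``- M M M`` / M lines ``i j k`` (0-based indices)."""
    lines = Path(path).read_text().splitlines()
    lines = [ln.strip() for ln in lines if ln.strip()]
    if not lines or not lines[0].startswith("-"):
        raise FileFormatError(f"{path}: expected '- N' header")
    try:
        nv = int(lines[0].lstrip("-").split()[0])
    except (ValueError, IndexError):
        raise FileFormatError(f"{path}: malformed vertex count line "
                              f"{lines[0]!r}") from None
    if len(lines) < nv + 2:
        raise FileFormatError(f"{path}: truncated file (expected {nv} "
                              "vertex lines)")
    verts = np.empty((nv, 3))
    for i in range(nv):
        parts = lines[1 + i].split()
        if len(parts) < 3:
            raise FileFormatError(f"{path}: vertex line {i} has "
                                  f"{len(parts)} fields (need >= 3)")
        verts[i] = [float(x) for x in parts[:3]]
    if not np.isfinite(verts).all():
        raise FileFormatError(f"{path}: non-finite vertex coordinates")
    tline = lines[1 + nv]
    if not tline.startswith("-"):
        raise FileFormatError(f"{path}: expected '- M M M' separator, got "
                              f"{tline!r}")
    try:
        nt = int(tline.lstrip("-").split()[0])
    except (ValueError, IndexError):
        raise FileFormatError(f"{path}: malformed triangle count line "
                              f"{tline!r}") from None
    if len(lines) < nv + 2 + nt:
        raise FileFormatError(f"{path}: truncated file (expected {nt} "
                              "triangle lines)")
    tris = np.empty((nt, 3), dtype=np.int64)
    for i in range(nt):
        parts = lines[2 + nv + i].split()
        if len(parts) != 3:
            raise FileFormatError(f"{path}: triangle line {i} has "
                                  f"{len(parts)} fields (need 3)")
        tris[i] = [int(x) for x in parts]
    if tris.size and (tris.min() < 0 or tris.max() >= nv):
        bad = int(np.abs(tris).max())
        raise FileFormatError(f"{path}: triangle index {bad} out of range "
                              f"[0, {nv})")
    return TriangleMesh(verts, tris)


def write_tri(path, mesh: TriangleMesh) -> None:
    """Write a .tri mesh (area-weighted vertex normals)."""
    vnorm = np.zeros_like(mesh.vertices)
    fn = mesh.face_normals * mesh.areas[:, None]
    for c in range(3):
        np.add.at(vnorm, mesh.triangles[:, c], fn)
    lens = np.linalg.norm(vnorm, axis=1, keepdims=True)
    lens[lens == 0] = 1.0
    vnorm /= lens
    with open(path, "w") as f:
        f.write(f"- {mesh.n_vertices}\n")
        for v, n in zip(mesh.vertices.tolist(), vnorm.tolist()):
            f.write(f"{v[0]!r} {v[1]!r} {v[2]!r} "
                    f"{n[0]!r} {n[1]!r} {n[2]!r}\n")
        f.write(f"- {mesh.n_triangles} {mesh.n_triangles} "
                f"{mesh.n_triangles}\n")
        for t in mesh.triangles:
            f.write(f"{t[0]} {t[1]} {t[2]}\n")


# ---------------------------------------------------------------------------
# .geom / .cond
# ---------------------------------------------------------------------------

GEOM_HEADER = re.compile(r"#\s*symbem\s+geom\s+1\.0")
COND_HEADER = re.compile(r"#\s*symbem\s+cond\s+1\.0")


def read_geom(path):
    """Parse a geometry file.

    Dialect (versioned header required)::

        # symbem geom 1.0
        Interfaces 3
        Cortex cortex.tri
        Skull skull.tri
        Scalp scalp.tri
        Domains 4
        Brain: -Cortex
        Skull: +Cortex -Skull
        Scalp: +Skull -Scalp
        Air: +Scalp

    Returns (interface names, mesh paths, domain dict name -> list of
    (sign, interface name)).  Mesh paths are resolved relative to the file.
    """
    path = Path(path)
    lines = [ln.strip() for ln in path.read_text().splitlines()
             if ln.strip()]
    if not lines or not GEOM_HEADER.match(lines[0]):
        raise FileFormatError(f"{path}: missing '# symbem geom 1.0' header")
    i = 1
    if not lines[i].startswith("Interfaces"):
        raise FileFormatError(f"{path}: expected 'Interfaces <n>'")
    n_if = int(lines[i].split()[1])
    names, paths = [], []
    for j in range(n_if):
        parts = lines[i + 1 + j].split(maxsplit=1)
        if len(parts) != 2:
            raise FileFormatError(f"{path}: malformed interface line "
                                  f"{lines[i + 1 + j]!r}")
        names.append(parts[0])
        paths.append(path.parent / parts[1])
    i += 1 + n_if
    if i >= len(lines) or not lines[i].startswith("Domains"):
        raise FileFormatError(f"{path}: expected 'Domains <n>'")
    n_dom = int(lines[i].split()[1])
    domains = {}
    for j in range(n_dom):
        ln = lines[i + 1 + j]
        if ":" not in ln:
            raise FileFormatError(f"{path}: malformed domain line {ln!r}")
        dname, members = ln.split(":", 1)
        entries = []
        for tok in members.split():
            if tok[0] not in "+-":
                raise FileFormatError(f"{path}: domain member {tok!r} must "
                                      "be signed (+Name or -Name)")
            if tok[1:] not in names:
                raise FileFormatError(f"{path}: unknown interface "
                                      f"{tok[1:]!r} in domain {dname!r}")
            entries.append((tok[0], tok[1:]))
        domains[dname.strip()] = entries
    return names, paths, domains


def read_cond(path) -> dict[str, float]:
    path = Path(path)
    lines = [ln.strip() for ln in path.read_text().splitlines()
             if ln.strip()]
    if not lines or not COND_HEADER.match(lines[0]):
        raise FileFormatError(f"{path}: missing '# symbem cond 1.0' header")
    out = {}
    for ln in lines[1:]:
        parts = ln.split()
        if len(parts) != 2:
            raise FileFormatError(f"{path}: malformed conductivity line "
                                  f"{ln!r}")
        out[parts[0]] = float(parts[1])
    return out


def read_head_model(geom_path, cond_path, check: bool = True) -> HeadModel:
    """Build a HeadModel from .geom + .cond, innermost interface first.

    The nested order is inferred from the domain descriptions: the domain
    bounded outside by interface S and inside by nothing is innermost.  A
    unit sanity warning is emitted when the scalp bounding radius exceeds
    1 m (coordinates are expected in meters).
    """
    import warnings

    names, paths, domains = read_geom(geom_path)
    conds = read_cond(cond_path)
    meshes = {n: read_tri(p) for n, p in zip(names, paths)}

    # order interfaces by enclosed volume (nested => strictly increasing)
    order = sorted(names, key=lambda n: abs(meshes[n].signed_volume()))
    # map: domain whose outer boundary is interface i
    domain_of_interface = {}
    for dname, members in domains.items():
        neg = [n for s, n in members if s == "-"]
        pos = [n for s, n in members if s == "+"]
        if len(neg) == 1:
            inner_ok = (not pos) or all(
                order.index(p) < order.index(neg[0]) for p in pos)
            if not inner_ok:
                raise FileFormatError(
                    f"{geom_path}: domain {dname!r} memberships are not "
                    "consistent with a nested ordering")
            domain_of_interface[neg[0]] = dname
        elif len(neg) > 1:
            raise FileFormatError(f"{geom_path}: domain {dname!r} has more "
                                  "than one outer boundary (non-nested)")
    sigmas = []
    for n in order:
        dname = domain_of_interface.get(n)
        if dname is None:
            raise FileFormatError(f"{geom_path}: no domain is bounded "
                                  f"outside by interface {n!r}")
        if dname not in conds:
            raise FileFormatError(f"{cond_path}: missing conductivity for "
                                  f"domain {dname!r}")
        sigmas.append(conds[dname])
    model = HeadModel(tuple(meshes[n] for n in order), tuple(sigmas),
                      names=tuple(domain_of_interface[n] for n in order))
    if model.scalp.bounding_radius() > 1.0:
        warnings.warn("scalp bounding radius exceeds 1 m; coordinates "
                      "should be in meters", stacklevel=2)
    if check:
        ok, rep = check_nesting(model)
        if not ok:
            raise FileFormatError(f"{geom_path}: interfaces are not "
                                  f"strictly nested: {rep}")
    return model


# ---------------------------------------------------------------------------
# ASCII matrices
# ---------------------------------------------------------------------------

def write_matrix(path, matrix: np.ndarray, symmetric: bool = False) -> None:
    m = np.asarray(matrix, dtype=np.float64)
    if m.ndim == 1:
        m = m[:, None]
    if symmetric:
        if m.shape[0] != m.shape[1] or not np.array_equal(m, m.T):
            raise ValueError("matrix is not symmetric")
    with open(path, "w") as f:
        f.write(f"{m.shape[0]} {m.shape[1]}"
                + (" symmetric\n" if symmetric else "\n"))
        if symmetric:
            for i in range(m.shape[0]):
                f.write(" ".join(repr(x)
                                 for x in m[i, :i + 1].tolist()) + "\n")
        else:
            for row in m.tolist():
                f.write(" ".join(repr(x) for x in row) + "\n")


def read_matrix(path) -> np.ndarray:
    lines = Path(path).read_text().splitlines()
    lines = [ln for ln in lines if ln.strip()]
    if not lines:
        raise FileFormatError(f"{path}: empty matrix file")
    head = lines[0].split()
    if len(head) not in (2, 3):
        raise FileFormatError(f"{path}: malformed matrix header "
                              f"{lines[0]!r}")
    rows, cols = int(head[0]), int(head[1])
    symmetric = len(head) == 3 and head[2] == "symmetric"
    vals = np.fromstring(" ".join(lines[1:]), sep=" ")
    if symmetric:
        if rows != cols:
            raise FileFormatError(f"{path}: symmetric matrix must be square")
        need = rows * (rows + 1) // 2
        if vals.size != need:
            raise FileFormatError(f"{path}: expected {need} lower-triangle "
                                  f"values, found {vals.size}")
        m = np.zeros((rows, cols))
        k = 0
        for i in range(rows):
            m[i, :i + 1] = vals[k:k + i + 1]
            k += i + 1
        m = m + np.tril(m, -1).T
    else:
        if vals.size != rows * cols:
            raise FileFormatError(f"{path}: expected {rows * cols} values, "
                                  f"found {vals.size}")
        m = vals.reshape(rows, cols)
    if not np.isfinite(m).all():
        raise FileFormatError(f"{path}: non-finite matrix entries")
    return m


# ---------------------------------------------------------------------------
# sensors / dipoles (plain whitespace-separated text)
# ---------------------------------------------------------------------------

def _numeric_rows(path):
    rows = []
    for lineno, ln in enumerate(Path(path).read_text().splitlines(),
                                start=1):
        ln = ln.split("#")[0].strip()
        if not ln:
            continue
        rows.append((lineno, ln.split()))
    if not rows:
        raise FileFormatError(f"{path}: empty input file")
    return rows


def read_dipoles(path):
    """Dipole file: one ``x y z qx qy qz`` row per dipole (SI units)."""
    positions, moments = [], []
    for lineno, parts in _numeric_rows(path):
        if len(parts) != 6:
            raise FileFormatError(f"{path}:{lineno}: expected 6 columns "
                                  f"(x y z qx qy qz), found {len(parts)}")
        vals = [float(x) for x in parts]
        positions.append(vals[:3])
        moments.append(vals[3:])
    return np.array(positions), np.array(moments)


def read_points(path, extra_columns: int = 0):
    """Point file: ``[name] x y z`` rows (EEG/IP electrodes, internal
    points); with ``extra_columns`` additional numeric fields (e.g. EIT
    injection currents).  Returns (names, points, extras)."""
    names, pts, extras = [], [], []
    need = 3 + extra_columns
    for lineno, parts in _numeric_rows(path):
        if len(parts) == need + 1:
            names.append(parts[0])
            parts = parts[1:]
        elif len(parts) == need:
            names.append("")
        else:
            raise FileFormatError(
                f"{path}:{lineno}: expected {need} numeric columns "
                f"(optionally preceded by a name), found {len(parts)}")
        vals = [float(x) for x in parts]
        pts.append(vals[:3])
        extras.append(vals[3:])
    return names, np.array(pts), np.array(extras)


def read_meg_sensors(path):
    """MEG file: ``x y z dx dy dz [weight] [channel]`` rows; rows sharing a
    channel label form one channel (weighted integration points)."""
    pts, dirs, wts, chans = [], [], [], []
    for lineno, parts in _numeric_rows(path):
        if len(parts) < 6 or len(parts) > 8:
            raise FileFormatError(f"{path}:{lineno}: expected 6-8 columns "
                                  f"(x y z dx dy dz [weight] [channel]), "
                                  f"found {len(parts)}")
        vals = [float(x) for x in parts[:6]]
        pts.append(vals[:3])
        dirs.append(vals[3:])
        wts.append(float(parts[6]) if len(parts) >= 7 else 1.0)
        chans.append(parts[7] if len(parts) == 8 else str(lineno))
    from .mesh import meg_sensors

    return meg_sensors(np.array(pts), np.array(dirs), np.array(wts),
                       np.array(chans))
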