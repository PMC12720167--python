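"""Synthetic folded-cortex ROI geometry.

The mapping method needs three geometric ingredients: a discretized cortical
patch (compartments = surface triangles), geodesic distances between
compartments along the surface, and a 2-D flattening for visualisation.
Real studies obtain the patch from an individual FEM head model; here a
parametric stand-in produces a disc-shaped patch with a sinusoidal fold so
that gyral-crown / sulcal-wall / fundus depth bands exist.

Units are mm throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components, shortest_path
from scipy.spatial import Delaunay


@dataclass
class ROIMesh:
    """Triangulated ROI surface with per-compartment depth labels.

    Compartments are the surface triangles; ``compartment_centers`` are their
    centroids.  ``depth`` is the vertical drop of each centroid below the
    crown envelope (0 = gyral crown, max ≈ twice the fold amplitude).
    """

    vertices: np.ndarray            # (V, 3)
    triangles: np.ndarray           # (K, 3) int
    compartment_centers: np.ndarray  # (K, 3)
    depth: np.ndarray               # (K,)
    roi_center: np.ndarray          # (3,)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        self.compartment_centers = np.asarray(self.compartment_centers, dtype=float)
        self.depth = np.asarray(self.depth, dtype=float)
        self.roi_center = np.asarray(self.roi_center, dtype=float)
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise ValueError("triangles must be (K, 3)")
        if self.n_compartments < 3:
            raise ValueError("need at least 3 compartments")
        if self.triangles.min() < 0 or self.triangles.max() >= len(self.vertices):
            raise ValueError("triangle index out of range")
        if np.any(self.depth < 0):
            raise ValueError("depth must be non-negative")

    @property
    def n_compartments(self) -> int:
        return len(self.triangles)


@dataclass
class GeodesicMatrix:
    """Pairwise geodesic distances (mm) between compartment centers."""

    dist: np.ndarray  # (K, K)

    def __post_init__(self) -> None:
        self.dist = np.asarray(self.dist, dtype=float)
        d = self.dist
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("dist must be square")
        if not np.all(np.isfinite(d)):
            raise ValueError("dist must be finite")
        if np.any(d < 0) or np.any(np.diag(d) != 0):
            raise ValueError("dist must be >= 0 with zero diagonal")
        if not np.allclose(d, d.T):
            raise ValueError("dist must be symmetric")

    @property
    def n_compartments(self) -> int:
        return len(self.dist)


def _hex_lattice(radius: float, spacing: float) -> np.ndarray:
    """Triangular lattice points covering a disc of given radius (origin included)."""
    dy = spacing * np.sqrt(3.0) / 2.0
    n_i = int(np.ceil((radius + spacing) / spacing)) + 1
    n_j = int(np.ceil((radius + spacing) / dy)) + 1
    pts = []
    for j in range(-n_j, n_j + 1):
        xoff = 0.5 * spacing if j % 2 else 0.0
        for i in range(-n_i, n_i + 1):
            pts.append((i * spacing + xoff, j * dy))
    pts = np.array(pts)
    return pts[np.hypot(pts[:, 0], pts[:, 1]) <= radius + 0.55 * spacing]


def fold_height(y: np.ndarray, fold_amplitude: float, fold_wavelength: float) -> np.ndarray:
    """Height field of the synthetic fold: z = A sin(2π y / λ)."""
    y = np.asarray(y, dtype=float)
    if fold_amplitude == 0:
        return np.zeros_like(y)
    return fold_amplitude * np.sin(2.0 * np.pi * y / fold_wavelength)


def build_synthetic_roi(
    n_compartments: int = 2200,
    fold_amplitude: float = 6.0,
    fold_wavelength: float = 12.0,
    radius: float = 30.0,
    seed: int = 0,
) -> ROIMesh:
    """Build a disc-shaped cortical patch with a sinusoidal fold.

    A triangular vertex lattice (spacing chosen to hit the requested
    compartment count) is jittered slightly, Delaunay-triangulated in the
    plane, and lifted by the height field ``z = A sin(2π y / λ)``.  Depth is
    the drop from the crown envelope (the maximum compartment height), so at
    least one compartment has depth exactly 0 and ``fold_amplitude = 0``
    yields a flat disc with all depths 0.

    Deterministic for a fixed seed.
    """
    if n_compartments < 3:
        raise ValueError("n_compartments must be >= 3")
    if radius <= 0 or fold_wavelength <= 0:
        raise ValueError("radius and fold_wavelength must be positive")
    if fold_amplitude < 0:
        raise ValueError("fold_amplitude must be >= 0")

    # triangle count of a lattice disc ~ 4 pi r^2 / (sqrt(3) h^2)
    spacing = float(np.sqrt(4.0 * np.pi * radius**2 / (np.sqrt(3.0) * n_compartments)))
    pts = _hex_lattice(radius, spacing)
    rng = np.random.default_rng(seed)
    interior = np.hypot(pts[:, 0], pts[:, 1]) < radius - 0.6 * spacing
    jitter = rng.uniform(-0.12, 0.12, size=pts.shape) * spacing
    pts = pts + jitter * interior[:, None]

    tri = Delaunay(pts)
    simplices = tri.simplices
    cent2d = pts[simplices].mean(axis=1)
    keep = np.hypot(cent2d[:, 0], cent2d[:, 1]) <= radius
    simplices = simplices[keep]

    z = fold_height(pts[:, 1], fold_amplitude, fold_wavelength)
    vertices = np.column_stack([pts, z])
    centers = vertices[simplices].mean(axis=1)
    # depth from the analytic height field at the centroid (not the sagged
    # triangle mean), so crest compartments sit at depth ~0 regardless of
    # triangle size; the argmax compartment has depth exactly 0
    zc = fold_height(centers[:, 1], fold_amplitude, fold_wavelength)
    depth = zc.max() - zc

    mesh = ROIMesh(
        vertices=vertices,
        triangles=simplices,
        compartment_centers=centers,
        depth=depth,
        roi_center=np.array([0.0, 0.0, float(centers[:, 2].max())]),
        meta={
            "fold_amplitude": fold_amplitude,
            "fold_wavelength": fold_wavelength,
            "radius": radius,
            "seed": seed,
            "lattice_spacing": spacing,
        },
    )
    return mesh


def depth_bands(
    mesh: ROIMesh, crown_frac: float = 0.25, fundus_frac: float = 0.75
) -> np.ndarray:
    """Classify compartments into 'crown' / 'wall' / 'fundus' by relative depth.

    Thresholds are fractions of the maximum depth; a flat mesh is all crown.
    """
    dmax = mesh.depth.max()
    labels = np.full(mesh.n_compartments, "wall", dtype=object)
    if dmax == 0:
        labels[:] = "crown"
        return labels
    rel = mesh.depth / dmax
    labels[rel <= crown_frac] = "crown"
    labels[rel >= fundus_frac] = "fundus"
    return labels


def _compartment_graph(mesh: ROIMesh, ring: int, adjacency: str = "vertex"):
    """Sparse weighted graph over compartments.

    adjacency='vertex' connects triangles sharing a vertex (default),
    'edge' only triangles sharing an edge; larger rings additionally
    connect each compartment to its BFS neighbourhood of that radius.  Edge
    weight is the Euclidean (chord) distance between centroids, so graph
    distances never undercut straight-line distance.
    """
    K = mesh.n_compartments
    nv = len(mesh.vertices)
    # vertex -> incident triangles
    rows = mesh.triangles.ravel()
    cols = np.repeat(np.arange(K), 3)
    inc = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(nv, K)).tocsr()
    adj = (inc.T @ inc).tocsr()  # entries count shared vertices
    adj.setdiag(0)
    adj.eliminate_zeros()
    if adjacency == "edge":
        adj.data[adj.data < 2] = 0  # an edge means two shared vertices
        adj.eliminate_zeros()
    elif adjacency != "vertex":
        raise ValueError("adjacency must be 'vertex' or 'edge'")
    reach = adj.copy()
    reach.data[:] = 1
    hop = adj.copy()
    hop.data[:] = 1
    for _ in range(ring - 1):
        reach = (reach + reach @ hop).tocsr()
        reach.data[:] = 1
    reach = reach.tocoo()
    i, j = reach.row, reach.col
    mask = i < j
    i, j = i[mask], j[mask]
    w = np.linalg.norm(
        mesh.compartment_centers[i] - mesh.compartment_centers[j], axis=1
    )
    g = coo_matrix((w, (i, j)), shape=(K, K))
    return g


def geodesic_distance_matrix(
    mesh: ROIMesh, ring: int = 2, adjacency: str = "vertex"
) -> GeodesicMatrix:
    """All-pairs geodesic distances between compartment centers.

    Shortest paths on a k-ring compartment graph with chord-length weights
    (Dijkstra).  ``adjacency`` picks the base graph (triangles sharing a
    vertex, or strictly an edge); ``ring=1`` is the plain adjacency graph.
    The default (vertex sharing, ring=2) keeps the metric stretch of the
    graph approximation within a few percent on well-shaped meshes.

    Raises if the mesh is disconnected, naming an isolated compartment.
    """
    if ring < 1:
        raise ValueError("ring must be >= 1")
    g = _compartment_graph(mesh, ring, adjacency)
    n_comp, labels = connected_components(g, directed=False)
    if n_comp > 1:
        counts = np.bincount(labels)
        small = np.argmin(counts)
        members = np.flatnonzero(labels == small)
        raise ValueError(
            f"mesh is disconnected: {n_comp} components; isolated component "
            f"contains compartments {members[:10].tolist()}"
        )
    dist = shortest_path(g, method="D", directed=False)
    dist = np.minimum(dist, dist.T)  # exact symmetry
    np.fill_diagonal(dist, 0.0)
    return GeodesicMatrix(dist=dist)


def flatten_mds(gd: GeodesicMatrix, seed: int = 0) -> np.ndarray:
    """Flatten the compartment geodesic metric to 2-D with metric MDS.

    Classical-MDS initialisation followed by SMACOF stress minimisation
    against the geodesic distances; deterministic for a fixed seed.  Used
    for reporting/plots only, never in the mapping computation.
    """
    from sklearn.manifold import smacof

    D = gd.dist
    K = len(D)
    if K < 3:
        raise ValueError("need at least 3 compartments to flatten")
    # classical MDS (Torgerson) init
    J = np.eye(K) - np.ones((K, K)) / K
    B = -0.5 * J @ (D**2) @ J
    evals, evecs = np.linalg.eigh(B)
    idx = np.argsort(evals)[::-1][:2]
    lam = np.clip(evals[idx], 0, None)
    init = evecs[:, idx] * np.sqrt(lam)
    # deterministic sign convention
    for c in range(2):
        m = np.argmax(np.abs(init[:, c]))
        if init[m, c] < 0:
            init[:, c] = -init[:, c]
    coords, _ = smacof(
        D,
        n_components=2,
        init=init,
        n_init=1,
        random_state=seed,
        normalized_stress=False,
    )
    return coords


def save_mesh(mesh: ROIMesh, path: str) -> None:
    """Write a mesh to HDF5 or CSV (full fidelity) or OFF/PLY/STL via trimesh.

    The CSV layout is one row per element: ``v,x,y,z`` for vertices and
    ``t,i0,i1,i2,depth`` for triangles, at full float precision.
    """
    path = str(path)
    if path.endswith(".csv"):
        with open(path, "w") as f:
            f.write("# roi_center," + ",".join(format(v, ".17g") for v in mesh.roi_center) + "\n")
            for v in mesh.vertices:
                f.write("v," + ",".join(format(x, ".17g") for x in v) + "\n")
            for tri, d in zip(mesh.triangles, mesh.depth):
                f.write(f"t,{tri[0]},{tri[1]},{tri[2]},{format(d, '.17g')}\n")
    elif path.endswith((".h5", ".hdf5")):
        import h5py

        with h5py.File(path, "w") as f:
            f.attrs["schema_version"] = 1
            f.create_dataset("vertices", data=mesh.vertices)
            f.create_dataset("triangles", data=mesh.triangles)
            f.create_dataset("depth", data=mesh.depth)
            f.create_dataset("roi_center", data=mesh.roi_center)
    else:
        import trimesh

        trimesh.Trimesh(
            vertices=mesh.vertices, faces=mesh.triangles, process=False
        ).export(path)


def load_mesh(path: str) -> ROIMesh:
    """Load a mesh previously written by :func:`save_mesh` (HDF5 or CSV)."""
    path = str(path)
    if path.endswith(".csv"):
        verts, tris, depths = [], [], []
        roi_center = np.zeros(3)
        with open(path) as f:
            for line in f:
                parts = line.strip().split(",")
                if parts[0] == "# roi_center":
                    roi_center = np.array([float(v) for v in parts[1:4]])
                elif parts[0] == "v":
                    verts.append([float(v) for v in parts[1:4]])
                elif parts[0] == "t":
                    tris.append([int(v) for v in parts[1:4]])
                    depths.append(float(parts[4]))
        vertices = np.array(verts)
        triangles = np.array(tris)
        depth = np.array(depths)
    else:
        import h5py

        with h5py.File(path, "r") as f:
            vertices = f["vertices"][...]
            triangles = f["triangles"][...]
            depth = f["depth"][...]
            roi_center = f["roi_center"][...]
    centers = vertices[triangles].mean(axis=1)
    return ROIMesh(
        vertices=vertices,
        triangles=triangles,
        compartment_centers=centers,
        depth=depth,
        roi_center=roi_center,
    )
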