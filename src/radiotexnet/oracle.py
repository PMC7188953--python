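"""Brute-force texture reference, written independently of the engine.

Everything here is literal enumeration in plain Python: explicit voxel-pair
loops for the co-occurrence matrix, run walking for run lengths, flood fill
for size zones, and per-voxel neighborhood scans for the gray-tone
difference table.  It is deliberately slow and only meant for tiny volumes;
tests check the vectorized engine against it to 1e-10.
"""

from __future__ import annotations

import math

from .preprocess import QuantizedVolume

_OFFSETS_13 = [
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
]

_EPS = 1e-12


def _grid(qvol: QuantizedVolume):
    lvl = qvol.levels
    msk = qvol.mask
    nx, ny, nz = lvl.shape
    voxels = [(x, y, z) for x in range(nx) for y in range(ny) for z in range(nz)
              if msk[x, y, z]]
    return lvl, msk, (nx, ny, nz), voxels


def _inside(shape, x, y, z):
    return 0 <= x < shape[0] and 0 <= y < shape[1] and 0 <= z < shape[2]


# ---------------------------------------------------------------------------

def _glcm(qvol: QuantizedVolume) -> dict:
    lvl, msk, shape, voxels = _grid(qvol)
    counts: dict = {}
    for (x, y, z) in voxels:
        for (dx, dy, dz) in _OFFSETS_13:
            u, v, w = x + dx, y + dy, z + dz
            if _inside(shape, u, v, w) and msk[u, v, w]:
                a, b = int(lvl[x, y, z]), int(lvl[u, v, w])
                counts[(a, b)] = counts.get((a, b), 0) + 1
                counts[(b, a)] = counts.get((b, a), 0) + 1
    total = sum(counts.values())
    p = {k: c / total for k, c in counts.items()}
    mu = sum(i * pij for (i, _), pij in p.items())
    sigma2 = sum((i - mu) ** 2 * pij for (i, _), pij in p.items())
    feats = {
        "energy": sum(pij ** 2 for pij in p.values()),
        "contrast": sum((i - j) ** 2 * pij for (i, j), pij in p.items()),
        "entropy": -sum(pij * math.log2(pij) for pij in p.values() if pij > 0),
        "homogeneity": sum(pij / (1 + abs(i - j)) for (i, j), pij in p.items()),
        "correlation": (sum((i - mu) * (j - mu) * pij for (i, j), pij in p.items())
                        / sigma2 if sigma2 > 0 else 0.0),
        "sumavg": sum((i + j) * pij for (i, j), pij in p.items()),
        "variance": sigma2,
        "dissimilarity": sum(abs(i - j) * pij for (i, j), pij in p.items()),
        "autocorr": sum(i * j * pij for (i, j), pij in p.items()),
    }
    return feats


# ---------------------------------------------------------------------------

def _size_style_features(counts: dict, n_vox: int, names: list, total_norm: float
                         ) -> dict:
    """Feature formulas shared by the run-length and size-zone families.

    ``counts`` maps (gray level, run length or zone size) -> count.
    """
    nr = sum(counts.values())
    sre = sum(c / j ** 2 for (_, j), c in counts.items()) / nr
    lre = sum(c * j ** 2 for (_, j), c in counts.items()) / nr
    row: dict = {}
    col: dict = {}
    for (i, j), c in counts.items():
        row[i] = row.get(i, 0) + c
        col[j] = col.get(j, 0) + c
    gln = sum(v ** 2 for v in row.values()) / nr
    rln = sum(v ** 2 for v in col.values()) / nr
    rp = nr / total_norm
    lgre = sum(c / i ** 2 for (i, _), c in counts.items()) / nr
    hgre = sum(c * i ** 2 for (i, _), c in counts.items()) / nr
    srlge = sum(c / (i ** 2 * j ** 2) for (i, j), c in counts.items()) / nr
    srhge = sum(c * i ** 2 / j ** 2 for (i, j), c in counts.items()) / nr
    lrlge = sum(c * j ** 2 / i ** 2 for (i, j), c in counts.items()) / nr
    lrhge = sum(c * i ** 2 * j ** 2 for (i, j), c in counts.items()) / nr
    mu_i = sum(i * c for (i, _), c in counts.items()) / nr
    mu_j = sum(j * c for (_, j), c in counts.items()) / nr
    glv = sum((i - mu_i) ** 2 * c for (i, _), c in counts.items()) / nr
    rlv = sum((j - mu_j) ** 2 * c for (_, j), c in counts.items()) / nr
    vals = [sre, lre, gln, rln, rp, lgre, hgre, srlge, srhge, lrlge, lrhge,
            glv, rlv]
    return dict(zip(names, vals))


def _glrlm(qvol: QuantizedVolume) -> dict:
    from .features import GLRLM_FEATURES

    lvl, msk, shape, voxels = _grid(qvol)
    counts: dict = {}
    for (dx, dy, dz) in _OFFSETS_13:
        for (x, y, z) in voxels:
            px, py, pz = x - dx, y - dy, z - dz
            if (_inside(shape, px, py, pz) and msk[px, py, pz]
                    and lvl[px, py, pz] == lvl[x, y, z]):
                continue  # not a run start: predecessor continues the run
            g = int(lvl[x, y, z])
            length = 1
            u, v, w = x + dx, y + dy, z + dz
            while _inside(shape, u, v, w) and msk[u, v, w] and lvl[u, v, w] == g:
                length += 1
                u, v, w = u + dx, v + dy, w + dz
            counts[(g, length)] = counts.get((g, length), 0) + 1
    n_vox = len(voxels)
    return _size_style_features(counts, n_vox, list(GLRLM_FEATURES),
                                total_norm=13.0 * n_vox)


def _glszm(qvol: QuantizedVolume) -> dict:
    from .features import GLSZM_FEATURES

    lvl, msk, shape, voxels = _grid(qvol)
    seen = set()
    counts: dict = {}
    nbrs = [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1)
            for dz in (-1, 0, 1) if (dx, dy, dz) != (0, 0, 0)]
    for start in voxels:
        if start in seen:
            continue
        g = int(lvl[start])
        stack = [start]
        seen.add(start)
        size = 0
        while stack:
            (x, y, z) = stack.pop()
            size += 1
            for (dx, dy, dz) in nbrs:
                nxt = (x + dx, y + dy, z + dz)
                if (nxt not in seen and _inside(shape, *nxt)
                        and msk[nxt] and int(lvl[nxt]) == g):
                    seen.add(nxt)
                    stack.append(nxt)
        counts[(g, size)] = counts.get((g, size), 0) + 1
    n_vox = len(voxels)
    return _size_style_features(counts, n_vox, list(GLSZM_FEATURES),
                                total_norm=float(n_vox))


def _ngtdm(qvol: QuantizedVolume) -> dict:
    lvl, msk, shape, voxels = _grid(qvol)
    ng = qvol.ng
    n = {i: 0 for i in range(1, ng + 1)}
    s = {i: 0.0 for i in range(1, ng + 1)}
    nbrs = [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1)
            for dz in (-1, 0, 1) if (dx, dy, dz) != (0, 0, 0)]
    for (x, y, z) in voxels:
        neigh = [int(lvl[x + dx, y + dy, z + dz]) for (dx, dy, dz) in nbrs
                 if _inside(shape, x + dx, y + dy, z + dz)
                 and msk[x + dx, y + dy, z + dz]]
        if not neigh:
            continue
        g = int(lvl[x, y, z])
        n[g] += 1
        s[g] += abs(g - sum(neigh) / len(neigh))
    n_tot = sum(n.values())
    cap = 1.0 / _EPS
    if n_tot == 0:
        return {"coarseness": cap, "contrast": 0.0, "busyness": 0.0,
                "complex": 0.0, "strength": 0.0}
    p = {i: n[i] / n_tot for i in n}
    occ = [i for i in p if p[i] > 0]
    ps = sum(p[i] * s[i] for i in occ)
    coarseness = min(1.0 / ps, cap) if ps > _EPS else cap
    if len(occ) > 1:
        contrast = (sum(p[i] * p[j] * (i - j) ** 2 for i in occ for j in occ)
                    / (len(occ) * (len(occ) - 1))
                    * sum(s[i] for i in occ) / n_tot)
    else:
        contrast = 0.0
    busy_den = sum(abs(i * p[i] - j * p[j]) for i in occ for j in occ)
    busyness = ps / busy_den if busy_den > _EPS else 0.0
    complexity = sum(abs(i - j) * (p[i] * s[i] + p[j] * s[j])
                     / (n_tot * (p[i] + p[j])) for i in occ for j in occ)
    s_tot = sum(s[i] for i in occ)
    strength = (sum((p[i] + p[j]) * (i - j) ** 2 for i in occ for j in occ)
                / s_tot if s_tot > _EPS else 0.0)
    return {"coarseness": coarseness, "contrast": contrast,
            "busyness": busyness, "complex": complexity, "strength": strength}


_FAMILIES = {"GLCM": _glcm, "GLRLM": _glrlm, "GLSZM": _glszm, "NGTDM": _ngtdm}


def texture_oracle(qvol: QuantizedVolume, family: str) -> dict:
    """Brute-force reference features for one texture family.

    ``family`` is one of GLCM, GLRLM, GLSZM, NGTDM; returns the same named
    features as the engine's corresponding operation.
    """
    if family not in _FAMILIES:
        raise ValueError(f"unknown texture family {family!r}")
    if not qvol.mask.any():
        raise ValueError("empty mask")
    return _FAMILIES[family](qvol)
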