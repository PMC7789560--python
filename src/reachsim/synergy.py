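"""Postural synergies: PCA over average reaching postures and principal
angles between PC subspaces.

All seven joint-space dimensions are angles in degrees, so the PCA is run
on mean-centered but unscaled data. The distance between the subspaces
spanned by the first *n* components of two PCAs is the largest principal
angle between them: 0° iff the spans coincide, 90° for orthogonal
subspaces, and it is the smallest rotation angle by which some direction
of one subspace must move to map it onto the other.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import subspace_angles
from sklearn.decomposition import PCA

from .metrics import ReachingPosture


@dataclass
class SynergyResult:
    group: str
    components: np.ndarray  # (7, 7) rows = orthonormal loadings, deg space
    explained_variance_ratio: np.ndarray  # (7,), descending, sums to 1
    n_samples: int


def run_pca(postures: list[ReachingPosture] | np.ndarray, group: str = "") -> SynergyResult:
    """PCA of average reaching postures (rows) in the 7-D joint space."""
    if isinstance(postures, np.ndarray):
        data = postures
        if not group:
            group = "data"
    else:
        data = np.array([p.angles for p in postures])
        if not group and postures:
            group = postures[0].group
    if data.ndim != 2 or data.shape[1] != 7:
        raise ValueError("postures must form an (n, 7) array")
    if len(data) < 2:
        raise ValueError("PCA needs at least two postures")
    if len(data) < 8:
        warnings.warn(
            f"only {len(data)} postures for a 7-D PCA; components are "
            "rank-deficient", stacklevel=2,
        )
    pca = PCA(n_components=7)
    pca.fit(data)
    return SynergyResult(
        group=group,
        components=pca.components_,
        explained_variance_ratio=pca.explained_variance_ratio_,
        n_samples=len(data),
    )


def cumulative_ev(result: SynergyResult, n: int) -> float:
    """Cumulated explained-variance ratio of the first ``n`` components."""
    if not 1 <= n <= 7:
        raise ValueError("n must lie in 1..7")
    return float(result.explained_variance_ratio[:n].sum())


def subspace_distance(a: SynergyResult, b: SynergyResult, n: int) -> float:
    """Largest principal angle (deg) between the spans of the first ``n``
    PCs of ``a`` and ``b``.

    Invariant to sign flips and any orthonormal re-basis of either
    subspace; symmetric in its arguments. Values of ``n`` outside 3–5 are
    allowed with a warning (the explained-variance profile makes 3–5 the
    informative range).
    """
    if not 1 <= n <= 7:
        raise ValueError("n must lie in 1..7")
    if not 3 <= n <= 5:
        warnings.warn(f"subspace distance at n={n} (informative range is 3-5)",
                      stacklevel=2)
    if n > a.components.shape[0] or n > b.components.shape[0]:
        raise ValueError("n exceeds the number of available components")
    basis_a = a.components[:n].T
    basis_b = b.components[:n].T
    angles = subspace_angles(basis_a, basis_b)  # descending, radians
    return float(np.rad2deg(angles[0]))


def synergy_to_json(results: dict[str, SynergyResult]) -> str:
    """Serializable bundle of components and explained-variance ratios."""
    import json

    return json.dumps(
        {
            g: {
                "components": np.round(r.components, 9).tolist(),
                "explained_variance_ratio": np.round(
                    r.explained_variance_ratio, 9
                ).tolist(),
                "n_samples": r.n_samples,
            }
            for g, r in results.items()
        },
        indent=1,
    )


def pairwise_distances(
    results: dict[str, SynergyResult], ns=(3, 4, 5)
) -> "object":
    """Tidy table of subspace distances for every group pair and n."""
    import itertools

    import pandas as pd

    rows = []
    for (ga, ra), (gb, rb) in itertools.combinations(results.items(), 2):
        for n in ns:
            rows.append((ga, gb, n, subspace_distance(ra, rb, n)))
    return pd.DataFrame(rows, columns=["group_a", "group_b", "n", "angle_deg"])
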