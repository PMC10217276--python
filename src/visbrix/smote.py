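"""SMOTE minority-class oversampling by same-class neighbor interpolation.

Each synthetic row is x_new = x_i + u * (x_nn - x_i), with u uniform on
[0, 1] and x_nn one of the k nearest same-class neighbors (Euclidean) of a
parent x_i. Per class, a multiplier f adds (f - 1) * size synthetic rows —
each original row parents exactly (f - 1) of them — so class counts scale
exactly and originals pass through unchanged. An optional continuous target
(e.g. °Brix) is interpolated with the same u so regression labels stay
consistent with the interpolated features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SmoteConfig", "smote"]


@dataclass
class SmoteConfig:
    """Per-grade multipliers (defaults reproduce 22/71/7 -> 66/71/28),
    neighbor count (auto-reduced to class size - 1) and seed."""

    multipliers: dict[int, int] = field(default_factory=lambda: {1: 3, 2: 1, 3: 4})
    k_neighbors: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if any(m < 1 for m in self.multipliers.values()):
            raise ValueError("multipliers must be >= 1")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")


def smote(
    features: np.ndarray,
    grades: np.ndarray,
    config: SmoteConfig,
    targets: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray] | tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Oversample each class to multiplier x its original size.

    Returns (augmented features, augmented grades) with the originals first,
    bit-identical, followed by the synthetic rows; plus augmented targets
    when ``targets`` is given. Deterministic per config seed.
    """
    x = np.atleast_2d(np.asarray(features, dtype=float))
    g = np.asarray(grades, dtype=int)
    if x.shape[0] != g.size:
        raise ValueError("features and grades must have equal length")
    y = None
    if targets is not None:
        y = np.asarray(targets, dtype=float)
        if y.shape != (x.shape[0],):
            raise ValueError("targets length must match features")

    rng = np.random.default_rng(config.seed)
    new_x, new_g, new_y = [], [], []
    for cls in sorted(np.unique(g)):
        mult = config.multipliers.get(int(cls), 1)
        if mult == 1:
            continue
        members = np.flatnonzero(g == cls)
        if members.size < 2:
            raise ValueError(
                f"class {cls} has {members.size} sample(s); cannot interpolate"
            )
        xc = x[members]
        k = min(config.k_neighbors, members.size - 1)
        # pairwise Euclidean distances within the class, self excluded
        d = np.linalg.norm(xc[:, None, :] - xc[None, :, :], axis=2)
        np.fill_diagonal(d, np.inf)
        nn = np.argsort(d, axis=1, kind="stable")[:, :k]
        for rep in range(mult - 1):
            for local_i in range(members.size):
                j = nn[local_i, rng.integers(k)]
                u = rng.uniform()
                new_x.append(xc[local_i] + u * (xc[j] - xc[local_i]))
                new_g.append(cls)
                if y is not None:
                    yi, yj = y[members[local_i]], y[members[j]]
                    new_y.append(yi + u * (yj - yi))

    if not new_x:
        out = (x.copy(), g.copy())
        return out + (y.copy(),) if y is not None else out
    aug_x = np.vstack([x, np.array(new_x)])
    aug_g = np.concatenate([g, np.array(new_g, dtype=int)])
    if y is not None:
        return aug_x, aug_g, np.concatenate([y, np.array(new_y)])
    return aug_x, aug_g
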