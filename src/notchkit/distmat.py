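"""Labelled symmetric distance matrices."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SYMMETRY_TOL = 1e-12


@dataclass
class DistanceMatrix:
    """Symmetric non-negative pairwise distances with row labels.

    ``kind`` records the recipe that produced the entries: raw ``p_distance``
    (fraction of differing comparable columns) or ``jc_protein`` (the
    20-state Jukes-Cantor multiple-hit correction of it).
    """

    labels: list
    values: np.ndarray
    kind: str = "p_distance"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if len(set(self.labels)) != n:
            raise ValueError("distance matrix labels must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("distance matrix contains non-finite entries")
        if np.any(self.values < 0):
            raise ValueError("distance matrix contains negative entries")
        if np.any(np.abs(np.diagonal(self.values)) > SYMMETRY_TOL):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(np.abs(self.values - self.values.T) > SYMMETRY_TOL):
            raise ValueError("distance matrix must be symmetric")

    @property
    def n(self) -> int:
        return len(self.labels)

    def __getitem__(self, pair) -> float:
        a, b = pair
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("label\t" + "\t".join(self.labels) + "\n")
            for label, row in zip(self.labels, self.values):
                fh.write(label + "\t" + "\t".join(format(v, ".10g") for v in row) + "\n")
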