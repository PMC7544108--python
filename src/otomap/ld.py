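"""Pairwise-r2 providers for clumping, locus definition and candidate expansion.

Two implementations share one small protocol:

- ``PanelLD``: r2 computed on demand from a genotype reference panel;
  pairs separated by more than ``window_bp`` (or on different chromosomes)
  are treated as r2 = 0, matching common practice.
- ``TableLD``: precomputed long-format (idA, idB, r2) pairs; a missing pair
  raises :class:`MissingLDError` rather than silently assuming independence.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._errors import MissingLDError
from .sim.panel import ReferencePanel


class PanelLD:
    def __init__(self, panel: ReferencePanel, window_bp: int = 1_000_000):
        self.panel = panel
        self.window_bp = int(window_bp)
        self.variants = panel.variants
        self._col = {v: i for i, v in enumerate(panel.variants["id"])}
        self._X = panel.standardized()
        self._pos = panel.variants["pos"].to_numpy()
        self._chrom = panel.variants["chrom"].to_numpy()

    def _index(self, snp_id: str) -> int:
        try:
            return self._col[snp_id]
        except KeyError:
            raise MissingLDError(f"variant {snp_id!r} not in the reference panel")

    def r2(self, id_a: str, id_b: str) -> float:
        ia, ib = self._index(id_a), self._index(id_b)
        if self._chrom[ia] != self._chrom[ib]:
            return 0.0
        if abs(int(self._pos[ia]) - int(self._pos[ib])) > self.window_bp:
            return 0.0
        n = self._X.shape[0]
        r = float(self._X[:, ia] @ self._X[:, ib]) / n
        return r * r

    def corr_matrix(self, ids: list[str]) -> np.ndarray:
        """Genotype correlation matrix for a set of variants."""
        idx = [self._index(s) for s in ids]
        n = self._X.shape[0]
        R = (self._X[:, idx].T @ self._X[:, idx]) / n
        np.fill_diagonal(R, 1.0)
        return R

    def partners(self, snp_id: str, r2_min: float) -> pd.DataFrame:
        """All panel variants with r2 > r2_min within the window (incl. self)."""
        i = self._index(snp_id)
        same = self._chrom == self._chrom[i]
        near = same & (np.abs(self._pos - self._pos[i]) <= self.window_bp)
        idx = np.flatnonzero(near)
        n = self._X.shape[0]
        r = (self._X[:, idx].T @ self._X[:, i]) / n
        r2 = r * r
        r2[idx == i] = 1.0
        keep = r2 > r2_min
        return pd.DataFrame(
            {
                "id": self.variants["id"].to_numpy()[idx[keep]],
                "chrom": self._chrom[idx[keep]],
                "pos": self._pos[idx[keep]],
                "r2": r2[keep],
            }
        )


class TableLD:
    """LD from a long-format table (idA, idB, r2) plus a variant table."""

    def __init__(self, pairs: pd.DataFrame, variants: pd.DataFrame):
        self.variants = variants.reset_index(drop=True)
        self._known = set(variants["id"])
        self._r2: dict[tuple[str, str], float] = {}
        for a, b, r2 in pairs[["idA", "idB", "r2"]].itertuples(index=False):
            self._r2[(a, b)] = float(r2)
            self._r2[(b, a)] = float(r2)
        self._by_pos = variants.set_index("id")

    @classmethod
    def from_tsv(cls, pairs_path, variants: pd.DataFrame) -> "TableLD":
        return cls(pd.read_csv(pairs_path, sep="\t"), variants)

    def r2(self, id_a: str, id_b: str) -> float:
        if id_a == id_b:
            return 1.0
        try:
            return self._r2[(id_a, id_b)]
        except KeyError:
            raise MissingLDError(f"no precomputed r2 for pair ({id_a}, {id_b})")

    def partners(self, snp_id: str, r2_min: float) -> pd.DataFrame:
        rows = [(snp_id, 1.0)]
        for (a, b), r2 in self._r2.items():
            if a == snp_id and r2 > r2_min:
                rows.append((b, r2))
        seen = set()
        uniq = [(i, r) for i, r in rows if not (i in seen or seen.add(i))]
        ids = [i for i, _ in uniq]
        info = self._by_pos.loc[ids]
        return pd.DataFrame(
            {
                "id": ids,
                "chrom": info["chrom"].to_numpy(),
                "pos": info["pos"].to_numpy(),
                "r2": [r for _, r in uniq],
            }
        )
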