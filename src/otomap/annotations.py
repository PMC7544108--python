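"""Binary SNP annotation matrices for stratified LD score regression."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._errors import AlignmentError, InvalidArgumentError

BASE_CATEGORY = "base"


@dataclass
class AnnotationMatrix:
    """Variants x categories binary membership.

    The first category must be the base category covering all SNPs.
    """

    categories: list[str]
    membership: np.ndarray  # (n_variants, n_categories) of 0/1

    def __post_init__(self) -> None:
        self.membership = np.asarray(self.membership)
        if self.membership.ndim != 2 or self.membership.shape[1] != len(self.categories):
            raise InvalidArgumentError("membership shape must match categories")
        if BASE_CATEGORY not in self.categories:
            raise InvalidArgumentError(f"a '{BASE_CATEGORY}' category is required")
        base = self.membership[:, self.categories.index(BASE_CATEGORY)]
        if not np.all(base == 1):
            raise InvalidArgumentError("base category must cover all SNPs")
        if not np.isin(self.membership, [0, 1]).all():
            raise InvalidArgumentError("membership must be binary")

    @property
    def n_variants(self) -> int:
        return self.membership.shape[0]

    @property
    def m_c(self) -> np.ndarray:
        """Per-category SNP counts (column sums)."""
        return self.membership.sum(axis=0)

    def column(self, category: str) -> np.ndarray:
        return self.membership[:, self.categories.index(category)]

    def check_aligned(self, n_variants: int) -> None:
        if self.n_variants != n_variants:
            raise AlignmentError(
                f"annotation rows ({self.n_variants}) != panel variants ({n_variants})"
            )

    @classmethod
    def base_only(cls, n_variants: int) -> "AnnotationMatrix":
        return cls([BASE_CATEGORY], np.ones((n_variants, 1), dtype=np.int8))

    @classmethod
    def from_masks(cls, masks: dict[str, np.ndarray]) -> "AnnotationMatrix":
        """Build from named boolean masks; the base category is added first."""
        names = list(masks)
        n = len(next(iter(masks.values())))
        cols = [np.ones(n, dtype=np.int8)]
        for name in names:
            m = np.asarray(masks[name]).astype(np.int8)
            if m.shape != (n,):
                raise InvalidArgumentError("all masks must share one variant universe")
            cols.append(m)
        return cls([BASE_CATEGORY] + names, np.column_stack(cols))

    @classmethod
    def from_beds(
        cls, variants: pd.DataFrame, beds: dict[str, pd.DataFrame]
    ) -> "AnnotationMatrix":
        """SNP membership by position overlap with BED intervals (0-based half-open)."""
        masks = {}
        for name, bed in beds.items():
            mask = np.zeros(len(variants), dtype=bool)
            for chrom, grp in bed.groupby("chrom"):
                sel = variants["chrom"].to_numpy() == str(chrom)
                if not sel.any():
                    continue
                pos0 = variants.loc[sel, "pos"].to_numpy() - 1  # 1-based SNP -> 0-based
                starts = grp["start"].to_numpy()
                ends = grp["end"].to_numpy()
                order = np.argsort(starts)
                starts, ends = starts[order], ends[order]
                idx = np.searchsorted(starts, pos0, side="right") - 1
                ok = idx >= 0
                ok[ok] &= pos0[ok] < ends[idx[ok]]
                # intervals may overlap; fall back to any-overlap check where needed
                hit = ok.copy()
                miss = ~hit
                if miss.any():
                    for i in np.flatnonzero(miss):
                        hit[i] = bool(np.any((starts <= pos0[i]) & (pos0[i] < ends)))
                sub = np.zeros(sel.sum(), dtype=bool)
                sub |= hit
                mask[sel] = sub
            masks[name] = mask
        return cls.from_masks(masks)
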