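"""Artificial community templates and their predicted TRF profiles.

The study design mixes known genotypes in controlled proportions: equal
abundance (detectability), MacArthur broken-stick (realistic rank-abundance
structure), and near-equal two-genotype pairs (resolution). Each template
induces, per enzyme channel, an ideal relative-abundance profile over the
genotypes' predicted complete TRF lengths.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .digest import TRFTable

__all__ = [
    "CommunityTemplate",
    "PredictedProfile",
    "equal_proportions",
    "broken_stick_proportions",
    "near_equal_pair",
    "build_predicted_profile",
    "default_study_templates",
]

_SUM_TOL = 1e-9


@dataclass(frozen=True)
class CommunityTemplate:
    """A named genotype → proportion composition (proportions sum to 1)."""

    name: str
    composition: dict[str, float]

    def __post_init__(self) -> None:
        props = list(self.composition.values())
        if not 2 <= len(props) <= 6:
            raise ValueError(f"{self.name}: templates hold 2–6 genotypes")
        if any(p <= 0 for p in props):
            raise ValueError(f"{self.name}: proportions must be strictly positive")
        if abs(sum(props) - 1.0) > _SUM_TOL:
            raise ValueError(f"{self.name}: proportions sum to {sum(props)}, not 1")

    @property
    def richness(self) -> int:
        return len(self.composition)

    def perturbed(self, cv: float, rng: np.random.Generator, name: str) -> "CommunityTemplate":
        """A pipetting-error replicate: proportions jittered by a lognormal
        factor of coefficient of variation `cv`, then renormalised."""
        if cv <= 0:
            return CommunityTemplate(name, dict(self.composition))
        sigma = float(np.sqrt(np.log1p(cv**2)))
        factors = rng.lognormal(mean=-sigma**2 / 2, sigma=sigma, size=self.richness)
        raw = np.array(list(self.composition.values())) * factors
        raw /= raw.sum()
        return CommunityTemplate(name, dict(zip(self.composition, raw.tolist())))


@dataclass(frozen=True)
class PredictedProfile:
    """Ideal TRF-length → relative-abundance profile for one enzyme channel."""

    enzyme_name: str
    dye: str
    abundance: dict[float, float]

    def __post_init__(self) -> None:
        if self.abundance:
            total = sum(self.abundance.values())
            if abs(total - 1.0) > _SUM_TOL:
                raise ValueError(f"profile abundances sum to {total}, not 1")
            if any(k <= 0 for k in self.abundance):
                raise ValueError("TRF lengths must be positive")

    def as_series(self) -> pd.Series:
        s = pd.Series(self.abundance, dtype=float).sort_index()
        s.index.name = "trf_bp"
        return s


def equal_proportions(genotype_ids: Sequence[str], name: str | None = None) -> CommunityTemplate:
    """Equal-abundance template: every genotype at 1/n."""
    ids = list(genotype_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate genotype ids")
    n = len(ids)
    if not 2 <= n <= 6:
        raise ValueError("equal-abundance templates need 2–6 genotypes")
    return CommunityTemplate(name or f"equal_{n}", {g: 1.0 / n for g in ids})


def broken_stick_proportions(n: int) -> list[float]:
    """MacArthur broken-stick expected proportions, descending.

    p_i = (1/n) * sum_{k=i..n} 1/k for ranks i = 1..n; sums to 1 exactly and
    is strictly decreasing.
    """
    if n < 2:
        raise ValueError("broken stick requires n >= 2")
    inv = [1.0 / k for k in range(1, n + 1)]
    return [sum(inv[i - 1:]) / n for i in range(1, n + 1)]


def near_equal_pair(
    genotype_ids: Sequence[str], delta: float, name: str | None = None
) -> CommunityTemplate:
    """Two genotypes at (0.5 + delta, 0.5 − delta), probing the resolution
    of the fingerprint for small abundance differences."""
    a, b = genotype_ids
    if not 0 <= delta < 0.5:
        raise ValueError("delta must lie in [0, 0.5)")
    return CommunityTemplate(
        name or f"pair_d{delta:g}", {a: 0.5 + delta, b: 0.5 - delta}
    )


def build_predicted_profile(
    template: CommunityTemplate,
    trf_table: TRFTable,
    enzyme_name: str,
) -> PredictedProfile:
    """Combine genotype proportions onto predicted complete TRF lengths.

    Genotypes sharing a TRF length sum (collision-safe); pseudo-TRFs carry
    zero abundance in the ideal prediction and are omitted.
    """
    abundance: dict[float, float] = {}
    dye = None
    for genotype_id, prop in template.composition.items():
        try:
            pred = trf_table.lookup(genotype_id, enzyme_name)
        except KeyError:
            raise KeyError(
                f"template {template.name!r}: no TRF prediction for genotype "
                f"{genotype_id!r} under enzyme {enzyme_name!r}"
            ) from None
        dye = pred.dye
        abundance[pred.complete_trf_bp] = abundance.get(pred.complete_trf_bp, 0.0) + prop
    return PredictedProfile(enzyme_name=enzyme_name, dye=dye or "", abundance=abundance)


def default_study_templates(
    genotype_ids: Sequence[str],
    pair_deltas: Sequence[float] = (0.0, 0.025, 0.05),
) -> list[CommunityTemplate]:
    """The nine-template design: equal and broken-stick templates at
    richness 4, 5 and 6, plus three near-equal two-genotype pairs.

    `genotype_ids` must hold six ids; richness-k templates use the first k.
    """
    ids = list(genotype_ids)
    if len(ids) != 6:
        raise ValueError("the study design uses exactly six genotypes")
    templates: list[CommunityTemplate] = []
    for k in (4, 5, 6):
        templates.append(equal_proportions(ids[:k], name=f"equal_{k}"))
    for k in (4, 5, 6):
        props = broken_stick_proportions(k)
        templates.append(
            CommunityTemplate(f"broken_stick_{k}", dict(zip(ids[:k], props)))
        )
    for i, d in enumerate(pair_deltas, start=1):
        templates.append(near_equal_pair(ids[:2], d, name=f"pair_{i}"))
    return templates


def templates_to_frame(templates: Sequence[CommunityTemplate]) -> pd.DataFrame:
    """Long-format TSV-ready table (template_name, genotype_id, proportion)."""
    return pd.DataFrame(
        {"template_name": t.name, "genotype_id": g, "proportion": p}
        for t in templates
        for g, p in t.composition.items()
    )
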