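"""Fat-replacement scoring scales and their map to the common 0–100 range.

Lower-limb muscle MRI studies grade intramuscular fat replacement on one of
several semi-quantitative ordinal scales (Mercuri-style visual scores) or on
the continuous Dixon fat fraction (FF, percent fat, 0–100).  To pool cohorts
scored on different scales, every native score is projected onto a common
0 (healthy muscle) – 100 (completely fat-replaced muscle) axis.

Discrete levels map linearly over their ordinal rank: a level with rank ``r``
among ``k`` ordered levels maps to ``100 * r / (k - 1)``.  Fat fraction passes
through unchanged since it already lives on [0, 100].
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class FatScale:
    """A muscle fat-replacement scoring scale.

    Parameters
    ----------
    id : str
        Short label, e.g. ``"0-4"`` or ``"FF"``.
    kind : str
        ``"discrete"`` (ordinal levels) or ``"continuous"`` (fat fraction).
    levels : tuple of str
        Ordered level labels, lowest severity first (discrete only).
    range : tuple of float
        ``(min, max)`` on the native scale.  Continuous scales must span
        exactly ``(0, 100)``.
    """

    id: str
    kind: str
    levels: tuple[str, ...] = field(default=())
    range: tuple[float, float] = (0.0, 100.0)

    def __post_init__(self) -> None:
        if self.kind not in ("discrete", "continuous"):
            raise ValueError(f"unknown scale kind {self.kind!r}")
        if self.kind == "discrete":
            if len(self.levels) < 2:
                raise ValueError("discrete scale needs >= 2 ordered levels")
            if len(set(self.levels)) != len(self.levels):
                raise ValueError("discrete levels must be distinct")
        else:
            if tuple(self.range) != (0.0, 100.0):
                raise ValueError("continuous scale range must be [0, 100]")

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def rank(self, level: str | float) -> int:
        """Ordinal rank (0-based) of a discrete level label or numeric value."""
        if self.kind != "discrete":
            raise ValueError(f"scale {self.id!r} is continuous; has no ranks")
        label = _canon_level(level)
        try:
            return self.levels.index(label)
        except ValueError:
            raise ValueError(
                f"score {level!r} is not a level of scale {self.id!r} "
                f"(levels: {list(self.levels)})"
            ) from None

    def normalize(self, score: str | float) -> float:
        """Map a native score onto the common 0–100 range."""
        if self.kind == "continuous":
            value = float(score)
            if not 0.0 <= value <= 100.0:
                raise ValueError(
                    f"fat fraction {value} outside [0, 100] for scale {self.id!r}"
                )
            return value
        r = self.rank(score)
        return 100.0 * r / (self.n_levels - 1)

    def normalize_rank(self, rank: float) -> float:
        """Map a (possibly fractional) ordinal rank onto 0–100.

        Fractional ranks arise from averaging, e.g. bilateral means or merged
        muscle groups.  Continuous scales treat ``rank`` as the FF value.
        """
        if self.kind == "continuous":
            if not 0.0 <= rank <= 100.0:
                raise ValueError(f"fat fraction {rank} outside [0, 100]")
            return float(rank)
        if not 0.0 <= rank <= self.n_levels - 1:
            raise ValueError(
                f"rank {rank} outside [0, {self.n_levels - 1}] for scale {self.id!r}"
            )
        return 100.0 * rank / (self.n_levels - 1)

    def quantize(self, ff: float) -> str | float:
        """Project a 0–100 fat fraction onto this scale's native levels.

        Discrete scales use equal-width bins over [0, 100]: ``k`` levels give
        ``k`` bins of width ``100 / k``; continuous scales return ``ff``
        unchanged.
        """
        if not 0.0 <= ff <= 100.0:
            raise ValueError(f"fat fraction {ff} outside [0, 100]")
        if self.kind == "continuous":
            return float(ff)
        k = self.n_levels
        idx = min(int(ff / (100.0 / k)), k - 1)
        return self.levels[idx]


def _canon_level(level: str | float) -> str:
    """Canonical string form of a level ('2.0' -> '2', '2a' stays '2a')."""
    if isinstance(level, str):
        text = level.strip()
        try:
            num = float(text)
        except ValueError:
            return text.lower()
        level = num
    if isinstance(level, (int, float)):
        if float(level).is_integer():
            return str(int(level))
        return str(level)
    return str(level)


#: The five scales found across published lower-limb muscle MRI cohorts:
#: 5-point Mercuri 0–4, 6-point Mercuri 0–5, 4-point Mercuri 1–4, 5-point
#: Mercuri with subcategories 2a/2b, and Dixon fat fraction.  The 2a/2b
#: subcategories are ordered 2a < 2b (adjacent increasing severities).
SCALES: dict[str, FatScale] = {
    "0-4": FatScale("0-4", "discrete", ("0", "1", "2", "3", "4"), (0, 4)),
    "0-5": FatScale("0-5", "discrete", ("0", "1", "2", "3", "4", "5"), (0, 5)),
    "1-4": FatScale("1-4", "discrete", ("1", "2", "3", "4"), (1, 4)),
    "2a2b": FatScale("2a2b", "discrete", ("0", "1", "2a", "2b", "3", "4"), (0, 4)),
    "FF": FatScale("FF", "continuous"),
}


def get_scale(scale_id: str) -> FatScale:
    try:
        return SCALES[scale_id]
    except KeyError:
        raise KeyError(
            f"unknown scale {scale_id!r}; known scales: {sorted(SCALES)}"
        ) from None


def normalize_scale(score: str | float, scale: FatScale | str) -> float:
    """Normalize a native score to the common 0–100 range (module-level API)."""
    if isinstance(scale, str):
        scale = get_scale(scale)
    return scale.normalize(score)


def quantize_to_scale(ff: float, scale: FatScale | str) -> str | float:
    """Project a 0–100 fat fraction onto a scale's native levels."""
    if isinstance(scale, str):
        scale = get_scale(scale)
    return scale.quantize(ff)
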