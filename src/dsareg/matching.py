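"""Control-point displacement estimation by block matching.

A ``w x w`` template around each control point of the live image is
compared against displaced patches of the mask image.  The integer
displacement minimizing the (polarity-adjusted) similarity cost is found
by hill climbing restarted from four initial displacements — a cheap
stand-in for exhaustive search that is reliable on the smooth match
surfaces that histogram measures produce at template sizes near 50 px.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, NamedTuple, Sequence

import numpy as np

from .imageio import as_gray_image
from .similarity import cost as _sim_cost

__all__ = ["MatchConfig", "Match", "extract_template", "hill_climb", "match_control_point", "match_all"]

#: 8-connected unit moves
_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass(frozen=True)
class MatchConfig:
    """Template-matching configuration.

    w : odd template side length (px).
    dmax : bound of the displacement search square, |dx|,|dy| <= dmax.
    starts : initial displacements of the restarted hill climbs.
    step_schedule : decreasing integer step sizes of each climb.
    """

    w: int = 51
    dmax: int = 20
    starts: tuple = ((5, 5), (5, -5), (-5, 5), (-5, -5))
    step_schedule: tuple = (4, 2, 1)

    def __post_init__(self):
        if self.w % 2 != 1 or self.w < 1:
            raise ValueError("template size w must be odd and positive")
        if self.dmax < max(max(abs(s[0]), abs(s[1])) for s in self.starts) + 1:
            raise ValueError("dmax must exceed the largest start displacement")
        if list(self.step_schedule) != sorted(self.step_schedule, reverse=True) or min(self.step_schedule) < 1:
            raise ValueError("step_schedule must be decreasing positive integers")


class Match(NamedTuple):
    """One matched control point: live point ``p``, mask point ``q = p + d``."""

    p: tuple
    q: tuple
    d: tuple
    score: float


def extract_template(img, center, w: int) -> np.ndarray:
    """The ``w x w`` patch centered at integer pixel ``center = (x, y)``.

    The full window must lie inside the image; callers respect the
    selector's border margin so this never truncates.
    """
    img = as_gray_image(img)
    x, y = int(round(center[0])), int(round(center[1]))
    h = (w - 1) // 2
    if x - h < 0 or y - h < 0 or x + h >= img.shape[1] or y + h >= img.shape[0]:
        raise IndexError(f"template window at ({x}, {y}) with w={w} exceeds image bounds {img.shape[::-1]}")
    return img[y - h : y + h + 1, x - h : x + h + 1]


def hill_climb(
    cost: Callable[[int, int], float],
    start=(0, 0),
    dmax: int = 20,
    step_schedule: Sequence[int] = (4, 2, 1),
):
    """Greedy descent of ``cost`` over the integer displacement square.

    From the current displacement the 8 neighbors at the current step size
    are probed (clamped to ``|dx|,|dy| <= dmax``); the climb moves to the
    strictly best improving neighbor, and when none improves the step
    schedule advances.  Cost evaluations are memoized.  Returns the final
    ``((dx, dy), cost)``; the returned cost never exceeds ``cost(start)``.
    """
    memo: dict = {}

    def ev(d):
        if d not in memo:
            memo[d] = cost(*d)
        return memo[d]

    cur = (int(np.clip(start[0], -dmax, dmax)), int(np.clip(start[1], -dmax, dmax)))
    cur_cost = ev(cur)
    for step in step_schedule:
        while True:
            best, best_cost = None, cur_cost
            for ux, uy in _NEIGHBORS:
                cand = (
                    int(np.clip(cur[0] + ux * step, -dmax, dmax)),
                    int(np.clip(cur[1] + uy * step, -dmax, dmax)),
                )
                if cand == cur:
                    continue
                c = ev(cand)
                if c < best_cost:
                    best, best_cost = cand, c
            if best is None:
                break
            cur, cur_cost = best, best_cost
    return cur, cur_cost


def match_control_point(live, mask, p, cfg: MatchConfig | None = None, measure: str = "ent") -> Match:
    """Displacement of one control point by multi-start hill climbing.

    The template is taken from the live image at ``p``; the cost of a
    displacement ``d`` is the polarity-adjusted ``measure`` between that
    template and the mask patch at ``p + d``.  Ties across starts keep the
    earliest start in the configured order.  Deterministic.
    """
    cfg = cfg or MatchConfig()
    live = as_gray_image(live)
    mask = as_gray_image(mask)
    tmpl = extract_template(live, p, cfg.w)
    px, py = int(round(p[0])), int(round(p[1]))

    memo: dict = {}

    def cost_fn(dx, dy):
        key = (dx, dy)
        if key not in memo:
            patch = extract_template(mask, (px + dx, py + dy), cfg.w)
            memo[key] = _sim_cost(measure, tmpl, patch)
        return memo[key]

    best_d, best_cost = None, np.inf
    for start in cfg.starts:
        d, c = hill_climb(cost_fn, start, cfg.dmax, cfg.step_schedule)
        if c < best_cost:
            best_d, best_cost = d, c
    return Match(p=(px, py), q=(px + best_d[0], py + best_d[1]), d=best_d, score=best_cost)


def match_all(live, mask, points, cfg: MatchConfig | None = None, measure: str = "ent") -> list[Match]:
    """Match every control point independently; input order is preserved."""
    cfg = cfg or MatchConfig()
    out = []
    for i, p in enumerate(points):
        try:
            out.append(match_control_point(live, mask, p, cfg, measure))
        except Exception as exc:
            raise RuntimeError(f"matching failed at control point index {i} ({tuple(p)})") from exc
    return out
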