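import numpy as np
import pytest

from larvatrack import ArenaSpec


@pytest.fixture
def arena() -> ArenaSpec:
    return ArenaSpec()


@pytest.fixture
def small_arena() -> ArenaSpec:
    """A compact arena that keeps renders cheap in unit tests."""
    return ArenaSpec(
        width_px=120,
        height_px=100,
        dish_center=(60.0, 50.0),
        dish_radius_px=45.0,
        food_center=(48.0, 40.0),
        food_radius_px=8.0,
        frame_interval_s=3.0,
    )


def flood_fill_components(mask: np.ndarray) -> list[set[tuple[int, int]]]:
    """Brute-force 8-connected components by BFS (independent oracle)."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    seen = np.zeros_like(mask)
    comps = []
    for r in range(h):
        for c in range(w):
            if not mask[r, c] or seen[r, c]:
                continue
            comp = set()
            stack = [(r, c)]
            seen[r, c] = True
            while stack:
                rr, cc = stack.pop()
                comp.add((rr, cc))
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        nr, nc = rr + dr, cc + dc
                        if (
                            0 <= nr < h
                            and 0 <= nc < w
                            and mask[nr, nc]
                            and not seen[nr, nc]
                        ):
                            seen[nr, nc] = True
                            stack.append((nr, nc))
            comps.append(comp)
    return comps


def oracle_particles(mask: np.ndarray, min_area: int = 1) -> set[tuple]:
    """(area, x, y) triples of the brute-force components, as a comparable set."""
    out = set()
    for comp in flood_fill_components(mask):
        if len(comp) < min_area:
            continue
        xs = [c for _, c in comp]
        ys = [r for r, _ in comp]
        out.add((len(comp), round(sum(xs) / len(xs), 9), round(sum(ys) / len(ys), 9)))
    return out
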