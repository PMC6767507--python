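"""Shared fixtures helpers and independent brute-force oracles.

The oracles here deliberately re-derive each quantity from first
principles (per-cell loops, flood fill, exhaustive pair enumeration) so
the vectorized implementations are checked against something that cannot
share their bugs.
"""

from __future__ import annotations

from collections import deque

import numpy as np

from autoredlist.grids import GridSpec
from autoredlist.habitat import EshSeries


def make_esh(masks, cell_size: float = 300.0, years=None) -> EshSeries:
    """Wrap one or more boolean masks as an EshSeries on a fresh grid."""
    masks = np.asarray(masks, dtype=bool)
    if masks.ndim == 2:
        masks = masks[None]
    n, rows, cols = masks.shape
    years = tuple(years) if years is not None else tuple(range(2000, 2000 + n))
    grid = GridSpec(rows=rows, cols=cols, cell_size=cell_size)
    return EshSeries(
        grid=grid,
        years=years,
        masks=masks,
        range_mask=np.ones((rows, cols), dtype=bool),
        empty_flag=not masks.any(),
    )


def aoo_oracle(mask: np.ndarray, cell_size: float, coarse: float) -> float:
    """Coarse-cell membership by per-cell center coordinates."""
    rows, _ = mask.shape
    seen = set()
    for r, c in zip(*np.nonzero(mask)):
        x = (c + 0.5) * cell_size
        y = (rows - r - 0.5) * cell_size
        seen.add((int(x // coarse), int(y // coarse)))
    return len(seen) * (coarse / 1000.0) ** 2


def flood_fill_components(mask: np.ndarray, adjacency: str) -> int:
    """Count connected components by breadth-first flood fill."""
    offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if adjacency == "queen":
        offsets += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    rows, cols = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    count = 0
    for r0 in range(rows):
        for c0 in range(cols):
            if not mask[r0, c0] or seen[r0, c0]:
                continue
            count += 1
            queue = deque([(r0, c0)])
            seen[r0, c0] = True
            while queue:
                r, c = queue.popleft()
                for dr, dc in offsets:
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < rows and 0 <= cc < cols and mask[rr, cc] and not seen[rr, cc]:
                        seen[rr, cc] = True
                        queue.append((rr, cc))
    return count


def clump_oracle(labels: np.ndarray, cell_size: float, dispersal_km: float) -> list[frozenset[int]]:
    """Exhaustive pairwise-distance transitive closure over fragments."""
    ids = sorted(set(labels.ravel()) - {0})
    cells = {i: list(zip(*np.nonzero(labels == i))) for i in ids}
    linked = {i: {i} for i in ids}
    for a in ids:
        for b in ids:
            if b <= a:
                continue
            best = min(
                np.hypot((ra - rb) * cell_size, (ca - cb) * cell_size)
                for ra, ca in cells[a]
                for rb, cb in cells[b]
            )
            gap = max(0.0, best - cell_size)
            if gap <= dispersal_km * 1000.0:
                linked[a].add(b)
                linked[b].add(a)
    # transitive closure by repeated merging
    groups: list[set[int]] = []
    for i in ids:
        merged = {i} | linked[i]
        overlapping = [g for g in groups if g & merged]
        for g in overlapping:
            merged |= g
            groups.remove(g)
        groups.append(merged)
    changed = True
    while changed:
        changed = False
        for i, g in enumerate(groups):
            for j in range(i + 1, len(groups)):
                if g & groups[j]:
                    groups[i] = g | groups.pop(j)
                    changed = True
                    break
            if changed:
                break
    return sorted((frozenset(g) for g in groups), key=min)


def gamma_oracle(x, y) -> tuple[int, int]:
    """Concordant/discordant pair counts by O(n²) enumeration."""
    n = len(x)
    c = d = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = x[i] - x[j]
            dy = y[i] - y[j]
            if dx * dy > 0:
                c += 1
            elif dx * dy < 0:
                d += 1
    return c, d


def redlist_oracle(eoo, aoo, n_pop, trend, frag, decline, mode) -> str:
    """Hand-written decision table for the six criteria at default thresholds.

    Written in plain if/else style, independent of the engine's banding
    helpers. ``trend`` is the percent change (negative = decline) used for
    both the A2 reduction and every C1 window; the D2 threat gate is the
    decline flag.
    """
    sev = {"LC": 0, "VU": 1, "EN": 2, "CR": 3}
    cats = ["LC"]
    red = -trend

    if red >= 80:
        cats.append("CR")
    elif red >= 50:
        cats.append("EN")
    elif red >= 30:
        cats.append("VU")

    b_gate = decline if mode == "decline_only" else (decline and frag)
    if b_gate:
        if eoo < 100:
            cats.append("CR")
        elif eoo < 5000:
            cats.append("EN")
        elif eoo < 20000:
            cats.append("VU")
        if aoo < 10:
            cats.append("CR")
        elif aoo < 500:
            cats.append("EN")
        elif aoo < 2000:
            cats.append("VU")

    if n_pop < 250 and red >= 25:
        cats.append("CR")
    elif n_pop < 2500 and red >= 20:
        cats.append("EN")
    elif n_pop < 10000 and red >= 10:
        cats.append("VU")

    if n_pop < 50:
        cats.append("CR")
    elif n_pop < 250:
        cats.append("EN")
    elif n_pop < 1000:
        cats.append("VU")

    if aoo < 20 and decline:
        cats.append("VU")

    return max(cats, key=lambda c: sev[c])
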