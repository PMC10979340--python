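"""Reproducible stratified train/validation/test splitting.

Split sizes follow the largest-remainder rule applied within each class,
so the realised sizes are a deterministic function of the class counts
and fractions (e.g. 94 participants at (0.55, 0.19, 0.26) always give
52/18/24); the seed only shuffles which members land where.
"""

from __future__ import annotations

from typing import Callable, Hashable, Sequence, TypeVar

import numpy as np

T = TypeVar("T")


def _largest_remainder(n: int, fractions: Sequence[float]) -> list[int]:
    raw = [n * f for f in fractions]
    counts = [int(np.floor(r)) for r in raw]
    remainder_order = sorted(
        range(len(fractions)), key=lambda i: (raw[i] - counts[i], -i), reverse=True
    )
    short = n - sum(counts)
    for i in remainder_order[:short]:
        counts[i] += 1
    return counts


def stratified_split(
    items: Sequence[T],
    fractions: tuple[float, float, float],
    seed: int,
    key: Callable[[T], Hashable] = lambda x: x,
) -> tuple[list[T], list[T], list[T]]:
    """Partition items into train/val/test preserving class balance.

    ``key`` extracts the stratification label from each item. Within
    each class the members are shuffled by ``seed`` and allocated by
    largest remainder, so the three parts are disjoint, exhaustive, and
    have class proportions within one member of the requested fractions.

    Raises when a class is too small to contribute at least one member
    to every split with a nonzero fraction.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {sum(fractions)}")
    if any(f < 0 for f in fractions):
        raise ValueError("fractions must be nonnegative")
    items = list(items)
    if not items:
        raise ValueError("cannot split an empty set")
    classes: dict[Hashable, list[T]] = {}
    for it in items:
        classes.setdefault(key(it), []).append(it)
    rng = np.random.default_rng(seed)
    parts: tuple[list[T], list[T], list[T]] = ([], [], [])
    for label in sorted(classes, key=repr):
        members = classes[label]
        counts = _largest_remainder(len(members), fractions)
        for i, (c, f) in enumerate(zip(counts, fractions)):
            if f > 0 and c == 0:
                raise ValueError(
                    f"class {label!r} (n={len(members)}) is too small to give "
                    f"every nonzero split at least one member"
                )
        order = rng.permutation(len(members))
        shuffled = [members[i] for i in order]
        start = 0
        for part, c in zip(parts, counts):
            part.extend(shuffled[start : start + c])
            start += c
    return parts
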