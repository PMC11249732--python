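"""Enumeration of block-maximal matches in a binary panel.

A *match block* is a set of at least ``W`` sequences that are identical over
at least ``L`` consecutive sites. Because a block is a two-dimensional object,
"maximal" can mean two things, and both objectives are implemented:

* **width-maximal** — at every end position, report the widest set of
  sequences still identical over a window of at least ``L`` sites, each time
  that set is about to change;
* **length-maximal** — report blocks that cannot be extended by one site in
  either direction while keeping at least ``W`` member sequences.

The normative semantics is the brute-force :func:`oracle_blocks`; the
PBWT-based scans are required (and tested) to reproduce it exactly.

Both finders accept an ``exclude_mask``: excluded cells match nothing, so no
block may cover them. This is how ground-truth clusters are extracted from
IBD-painted interim panels in which heterozygous filler cells must not match.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

import numpy as np

from .pbwt import advance, init_state

__all__ = [
    "MatchBlock",
    "find_width_maximal",
    "find_length_maximal",
    "oracle_blocks",
    "quickselect",
]


@dataclass(frozen=True)
class MatchBlock:
    """A half-open site interval, a member set, and the shared consensus."""

    start: int
    end: int
    members: frozenset
    consensus: str

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def width(self) -> int:
        return len(self.members)

    def cells(self) -> int:
        """Number of (member, site) cells the block covers."""
        return self.width * self.length


def _sort_key(b: MatchBlock):
    return (b.start, b.end, min(b.members))


def _consensus(values, member, start, end) -> str:
    return "".join("01"[int(v)] for v in values[member, start:end])


def _finalize(values, raw):
    """Deduplicate (start, end, member-set) triples and emit sorted blocks."""
    out = []
    for (s, e, members) in sorted(raw, key=lambda t: (t[0], t[1], min(t[2]))):
        out.append(
            MatchBlock(s, e, frozenset(members), _consensus(values, min(members), s, e))
        )
    return out


def _panel_arrays(panel, exclude_mask):
    values = np.asarray(getattr(panel, "values", panel))
    if exclude_mask is not None:
        exclude_mask = np.asarray(exclude_mask, dtype=bool)
        if exclude_mask.shape != values.shape:
            raise ValueError("exclude_mask must have the same shape as the panel")
    return values, exclude_mask


def find_width_maximal(panel, L: int, W: int, exclude_mask=None):
    """All width-maximal blocks with length >= L and width >= W.

    At each end position ``e`` the PBWT sort is partitioned into runs of
    consecutive entries whose divergence is at most ``e - L`` (entries with a
    larger divergence separate matches). A run ``S`` of at least ``W``
    sequences is identical over ``[s, e)`` where ``s`` is the largest
    divergence inside the run; the block is reported exactly when ``S`` is
    about to lose a member — some member carries a different allele (or an
    excluded cell) at column ``e`` — or the panel ends.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    if W < 2:
        raise ValueError("W must be >= 2")
    values, excl = _panel_arrays(panel, exclude_mask)
    M, N = values.shape
    if W > M or L > N:
        return []

    raw = set()
    state = init_state(M)
    for e in range(1, N + 1):
        state = advance(
            state,
            values[:, e - 1],
            missing=None if excl is None else excl[:, e - 1],
        )
        if e < L:
            continue
        a, d = state.a, state.d
        sep = d > e - L  # run boundaries (d[0] = e qualifies, so runs align)
        starts = np.flatnonzero(sep)
        bounds = np.append(starts, M)
        for lo, hi in zip(bounds[:-1], bounds[1:]):  # run = a[lo:hi]
            if hi - lo < W:
                continue
            s = int(d[lo + 1 : hi].max())
            members = a[lo:hi]
            if e < N:
                col = values[members, e]
                ok = None if excl is None else excl[members, e]
                survives = (col == col[0]).all() and (ok is None or not ok.any())
                if survives:
                    continue
            raw.add((s, e, frozenset(int(m) for m in members)))
    return _finalize(values, raw)


def find_length_maximal(panel, L: int, W: int, exclude_mask=None):
    """All length-maximal blocks with length >= L and width >= W.

    A reported block ``(s, e, S)`` satisfies: ``S`` is *all* sequences
    identical on ``[s, e)``, ``|S| >= W``, ``e - s >= L``, and no subset of at
    least ``W`` members remains identical when the window grows to
    ``[s-1, e)`` or ``[s, e+1)``.

    At each end ``e`` the candidate sets form a laminar family: the runs at
    divergence threshold ``e - L``, recursively split at their internal
    maximum divergence. A node with internal maximum ``m`` is the maximal set
    for ``[m, e)``; it is left-unextendable iff every split part has fewer
    than ``W`` members, and right-unextendable iff fewer than ``W`` members
    share a (non-excluded) allele at column ``e``.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    if W < 2:
        raise ValueError("W must be >= 2")
    values, excl = _panel_arrays(panel, exclude_mask)
    M, N = values.shape
    if W > M or L > N:
        return []

    raw = set()
    state = init_state(M)
    for e in range(1, N + 1):
        state = advance(
            state,
            values[:, e - 1],
            missing=None if excl is None else excl[:, e - 1],
        )
        if e < L:
            continue
        a, d = state.a, state.d
        sep = d > e - L
        starts = np.flatnonzero(sep)
        bounds = np.append(starts, M)
        stack = [
            (int(lo), int(hi))
            for lo, hi in zip(bounds[:-1], bounds[1:])
            if hi - lo >= W
        ]
        while stack:
            lo, hi = stack.pop()
            inner = d[lo + 1 : hi]
            m = int(inner.max()) if inner.size else 0
            # children: sub-runs at threshold m - 1 (split where d == m)
            cuts = lo + 1 + np.flatnonzero(inner >= m) if m > 0 else np.arange(lo + 1, hi)
            cbounds = np.concatenate([[lo], cuts, [hi]])
            child_sizes = np.diff(cbounds)
            left_ok = bool((child_sizes < W).all())
            for clo, chi in zip(cbounds[:-1], cbounds[1:]):
                if chi - clo >= W and (chi - clo) < (hi - lo):
                    stack.append((int(clo), int(chi)))
            if not left_ok:
                continue
            members = a[lo:hi]
            if e < N:
                col = values[members, e]
                if excl is not None:
                    col = col[~excl[members, e]]
                if col.size and max(
                    int((col == 0).sum()), int((col != 0).sum())
                ) >= W:
                    continue  # right-extendable
            raw.add((m, e, frozenset(int(x) for x in members)))
    return _finalize(values, raw)


def quickselect(values, c: int):
    """The ``c``-th smallest element (1-based rank), duplicates counted.

    Average linear time via random-pivot partitioning; used to locate order
    statistics of divergence values without fully sorting them.
    """
    vals = list(values)
    if not 1 <= c <= len(vals):
        raise ValueError(f"rank c={c} out of range for {len(vals)} values")
    rng = random.Random(0x5EED)
    k = c - 1
    lo, hi = 0, len(vals)
    while True:
        if hi - lo == 1:
            return vals[lo]
        pivot = vals[rng.randrange(lo, hi)]
        lt = [v for v in vals[lo:hi] if v < pivot]
        eq = [v for v in vals[lo:hi] if v == pivot]
        gt = [v for v in vals[lo:hi] if v > pivot]
        if k < lo + len(lt):
            vals[lo : lo + len(lt)] = lt
            hi = lo + len(lt)
        elif k < lo + len(lt) + len(eq):
            return pivot
        else:
            vals[lo : lo + len(lt) + len(eq)] = lt + eq
            vals[lo + len(lt) + len(eq) : hi] = gt
            lo = lo + len(lt) + len(eq)


# ---------------------------------------------------------------------------
# Brute-force oracle (normative definition; quadratic, small panels only)
# ---------------------------------------------------------------------------


def _window_classes(values, excl, s, e, W):
    """Group row indices identical (and fully included) on [s, e)."""
    groups = {}
    for i in range(values.shape[0]):
        if excl is not None and excl[i, s:e].any():
            continue
        groups.setdefault(tuple(values[i, s:e]), []).append(i)
    return [g for g in groups.values() if len(g) >= W]


def _agree_at(values, excl, rows, col):
    if excl is not None and excl[rows, col].any():
        return False
    v = values[rows, col]
    return bool((v == v[0]).all())


def oracle_blocks(panel, L: int, W: int, objective: str = "width", exclude_mask=None):
    """Literal brute-force enumeration of block-maximal matches.

    Implements the definitions of :func:`find_width_maximal` and
    :func:`find_length_maximal` by direct window enumeration; serves as the
    independent reference the PBWT scans are validated against.
    """
    if objective not in ("width", "length"):
        raise ValueError(f"unknown objective {objective!r}")
    values, excl = _panel_arrays(panel, exclude_mask)
    M, N = values.shape
    raw = set()
    if W > M or L > N:
        return []
    if objective == "width":
        for e in range(L, N + 1):
            for rows in _window_classes(values, excl, e - L, e, W):
                rows_arr = np.asarray(rows)
                s = e - L
                while s > 0 and _agree_at(values, excl, rows_arr, s - 1):
                    s -= 1
                if e == N or not _agree_at(values, excl, rows_arr, e):
                    raw.add((s, e, frozenset(rows)))
    else:
        for s in range(0, N - L + 1):
            for e in range(s + L, N + 1):
                for rows in _window_classes(values, excl, s, e, W):
                    rows_arr = np.asarray(rows)
                    if s > 0 and _extendable(values, excl, rows_arr, s - 1, W):
                        continue
                    if e < N and _extendable(values, excl, rows_arr, e, W):
                        continue
                    raw.add((s, e, frozenset(rows)))
    return _finalize(values, raw)


def _extendable(values, excl, rows, col, W):
    """Does some subset of >= W rows share a non-excluded allele at col?"""
    ok = rows if excl is None else rows[~excl[rows, col]]
    if ok.size < W:
        return False
    v = values[ok, col]
    return max(int((v == 0).sum()), int((v != 0).sum())) >= W
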