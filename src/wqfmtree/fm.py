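"""Fiduccia-Mattheyses refinement of a bipartition.

A pass repeatedly transfers the unlocked item whose move has the maximum
gain (exact score delta), locking each item after it moves, until no legal
move remains; the pass then rolls back to the move prefix with the highest
cumulative score.  Passes repeat until one fails to improve the score
strictly, or a pass budget is exhausted.  Moves that would empty a side are
illegal, so both sides always keep at least one item.

Gain ties are broken toward the move that leaves the two sides more
balanced, then by stable item order, making runs deterministic.  Gains are
always computed as differences of two full score evaluations, so the
optional full-rescore debug mode coincides with the production path.

A pass may walk through unbalanced states, but the accepted prefix must
leave at least ``min_side`` items (default 2) on each side.  A singleton
side scores exactly 0 (one item forms no quartet pair), so on conflicted
inputs an isolate-one-item split can look optimal; accepting it makes no
progress -- the isolated item is wrapped in a dummy that behaves
identically in the same-sized remainder subproblem, and the recursion
cycles.  Requiring two items per accepted side makes every divide step
strictly shrink both subproblems.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .dummy import WeightAssignment, sort_items
from .scoring import Bipartition, ScoringSession

DEFAULT_MAX_PASSES = 20


@dataclass
class FMConfig:
    max_passes: int = DEFAULT_MAX_PASSES
    debug_full_rescore: bool = True  # informational: gains are always exact


@dataclass
class MoveRecord:
    item: object
    gain: float
    cumulative: float


@dataclass
class FMPassState:
    """Log of one FM pass: applied moves and the best prefix found."""

    initial_score: float
    moves: list[MoveRecord] = field(default_factory=list)
    best_prefix: int = 0
    best_score: float = float("-inf")


def fm_pass(bipartition: Bipartition, gene_trees, weights: WeightAssignment,
            session: ScoringSession | None = None, min_side: int = 2):
    """One FM pass from ``bipartition``.

    Returns ``(best_bipartition, best_score, state)`` where the bipartition
    is the best move prefix leaving >= ``min_side`` items per side (the
    unchanged input when no such prefix improves on it).
    """
    if session is None:
        session = ScoringSession(gene_trees, weights)
    current = bipartition
    session.set_bipartition(current)
    score = session.score()
    state = FMPassState(initial_score=score, best_score=score)
    best_bip = current
    locked: set[int] = set()
    cumulative = score
    while True:
        sides = [(it, "A") for it in current.A] + [(it, "B") for it in current.B]
        candidates = []
        for it, side in sides:
            if id(it) in locked:
                continue
            src = len(current.A) if side == "A" else len(current.B)
            if src < 2:
                continue  # move would empty its source side
            candidates.append((it, side))
        if not candidates:
            break
        best_move = None
        best_key = None
        for it, side in sort_items_with_side(candidates):
            g = session.gain_from_current(it, cumulative)
            na, nb = len(current.A), len(current.B)
            if side == "A":
                na, nb = na - 1, nb + 1
            else:
                na, nb = na + 1, nb - 1
            key = (g, min(na, nb))
            if best_key is None or key > best_key:
                best_key, best_move = key, (it, g)
        it, g = best_move
        current = current.move(it)
        session.set_bipartition(current)
        locked.add(id(it))
        cumulative += g
        state.moves.append(MoveRecord(it, g, cumulative))
        balanced = min(len(current.A), len(current.B)) >= min_side
        if balanced and cumulative > state.best_score + 1e-12:
            state.best_score = cumulative
            state.best_prefix = len(state.moves)
            best_bip = current
    session.set_bipartition(best_bip)
    return best_bip, state.best_score, state


def sort_items_with_side(candidates):
    """Stable deterministic candidate order (real items by label, then dummies)."""
    order = {id(it): i for i, it in enumerate(sort_items([c[0] for c in candidates]))}
    return sorted(candidates, key=lambda c: order[id(c[0])])


def refine(initial: Bipartition, gene_trees, weights: WeightAssignment,
           max_passes: int = DEFAULT_MAX_PASSES,
           session: ScoringSession | None = None,
           min_side: int = 2) -> Bipartition:
    """Run FM passes until a pass yields no strict improvement.

    The returned bipartition never scores below the initial one.
    """
    if session is None:
        session = ScoringSession(gene_trees, weights)
    current = initial
    session.set_bipartition(current)
    score = session.score()
    for _ in range(max_passes):
        new_bip, new_score, _state = fm_pass(current, gene_trees, weights,
                                             session, min_side=min_side)
        if new_score <= score + 1e-12:
            break
        current, score = new_bip, new_score
    return current
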