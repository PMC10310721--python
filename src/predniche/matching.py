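"""Reconciling prey binomials against a reference species list.

Diet studies record prey names with spelling variants and outdated
taxonomy. Matching uses optimal string alignment (OSA) — the restricted
Damerau-Levenshtein edit distance allowing insertions, deletions,
substitutions and adjacent transpositions, with no substring edited twice —
normalized to a unit-scale similarity, followed by a two-threshold triage:

* similarity 1 (after case/whitespace normalization) -> ``exact``;
* similarity > ``high`` (default 0.9) -> ``resolved_spelling``;
* ``low`` < similarity <= ``high`` -> ``needs_review`` (resolved only via an
  external arbiter callback, defaulting to ``unknown``);
* similarity <= ``low`` (default 0.5) -> ``unknown`` — excluded from all
  downstream diversity counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence


logger = logging.getLogger(__name__)


def osa_distance(a: str, b: str, cap: int | None = None) -> int:
    """Optimal string alignment (restricted Damerau-Levenshtein) distance.

    Unit-cost insertions, deletions, substitutions, and transpositions of
    adjacent characters; unlike the unrestricted Damerau-Levenshtein metric a
    substring is never edited twice, so e.g. ``osa("ca", "abc") == 3``.

    ``cap`` allows early abort: when the true distance exceeds it, any value
    > ``cap`` may be returned (the exact distance is not computed).
    """
    la, lb = len(a), len(b)
    if la == 0:
        return lb
    if lb == 0:
        return la
    # DP over prefix lengths; keep three rows for the transposition lookback.
    prev2 = None
    prev = list(range(lb + 1))
    for i in range(1, la + 1):
        cur = [i] + [0] * lb
        for j in range(1, lb + 1):
            cost = 0 if a[i - 1] == b[j - 1] else 1
            cur[j] = min(
                prev[j] + 1,        # deletion
                cur[j - 1] + 1,     # insertion
                prev[j - 1] + cost, # substitution / match
            )
            if (
                i > 1
                and j > 1
                and a[i - 1] == b[j - 2]
                and a[i - 2] == b[j - 1]
            ):
                cur[j] = min(cur[j], prev2[j - 2] + 1)
        if cap is not None and min(cur) > cap:
            return cap + 1
        prev2, prev = prev, cur
    return prev[lb]


def normalized_similarity(a: str, b: str) -> float:
    """1 - OSA distance / max length, in [0, 1]; two empty strings match."""
    m = max(len(a), len(b))
    if m == 0:
        return 1.0
    return 1.0 - osa_distance(a, b) / m


@dataclass
class MatchReport:
    query: str
    best_match: str | None
    similarity: float
    disposition: str  # exact | resolved_spelling | needs_review | unknown


def _normalize(name: str) -> str:
    return " ".join(name.split()).lower()


def reconcile_binomials(
    queries: Iterable[str],
    reference: Sequence[str],
    high: float = 0.9,
    low: float = 0.5,
    arbiter: Callable[[str, str, float], str | None] | None = None,
) -> list[MatchReport]:
    """Triage each query against the reference list.

    Comparison is case-insensitive after whitespace normalization. Ties on
    best similarity are broken lexicographically with a logged warning (the
    matcher never silently maps several candidates to one query).
    ``arbiter(query, candidate, similarity)`` may resolve ``needs_review``
    cases; without one they default to ``unknown``, mirroring conservative
    exclusion of unresolvable names.
    """
    if not reference:
        raise ValueError("reference list must be non-empty")
    ref_norm = [(_normalize(r), r) for r in reference]
    lookup = {}
    for norm, orig in ref_norm:
        lookup.setdefault(norm, orig)

    reports: list[MatchReport] = []
    for query in queries:
        qn = _normalize(query)
        if qn in lookup:
            reports.append(MatchReport(query, lookup[qn], 1.0, "exact"))
            continue
        lq = len(qn)
        best_sim = -1.0
        ties_raw: list[tuple[str, str]] = []
        for rn, orig in ref_norm:
            m = max(lq, len(rn))
            if m == 0:
                continue
            # |len(a)-len(b)| lower-bounds the distance: prune candidates
            # whose best achievable similarity is below the current best
            if 1.0 - abs(lq - len(rn)) / m < best_sim:
                continue
            cap = int((1.0 - best_sim) * m) + 1 if best_sim > 0 else None
            dist = osa_distance(qn, rn, cap=cap)
            sim = 1.0 - dist / m
            if sim > best_sim:
                best_sim, ties_raw = sim, [(rn, orig)]
            elif sim == best_sim:
                ties_raw.append((rn, orig))
        ties = sorted(ties_raw)
        if len(ties) > 1:
            logger.warning(
                "query %r ties at similarity %.3f among %d candidates; "
                "choosing lexicographically first (%r)",
                query, best_sim, len(ties), ties[0][1],
            )
        best = ties[0][1]
        if best_sim > high:
            reports.append(MatchReport(query, best, best_sim, "resolved_spelling"))
        elif best_sim > low:
            resolved = arbiter(query, best, best_sim) if arbiter else None
            if resolved is not None:
                reports.append(
                    MatchReport(query, resolved, best_sim, "resolved_spelling")
                )
            else:
                reports.append(MatchReport(query, best, best_sim, "needs_review"))
        else:
            reports.append(MatchReport(query, None, best_sim, "unknown"))
    return reports


def resolved_names(reports: Iterable[MatchReport]) -> list[str]:
    """Reference names usable downstream (exact or resolved spellings)."""
    return [
        r.best_match
        for r in reports
        if r.disposition in {"exact", "resolved_spelling"} and r.best_match
    ]
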