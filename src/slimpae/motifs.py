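"""Motif localization and adaptive-threshold filtering.

Two localization strategies are provided:

* ``minipae`` — anchor the call at the residue with the lowest inter-chain
  PAE and extend it to the maximal contiguous run of residues whose
  per-residue minimum inter-chain PAE stays within ``delta`` (default 3.0 A)
  of the global minimum.  One call per prediction by default, since MiniPAE
  is defined by a single global minimum; secondary low-PAE islands can be
  requested with ``all_islands=True``.
* ``alphaslim`` — one call per maximal contiguous run of strictly positive
  AlphaSLiM values, each scored by its maximum.

Calls are filtered with the screen-size-adaptive MiniPAE threshold

    threshold(n) = 30.29 * n**-0.2803 - 3.82   [A]

which tracks the expected minimum MiniPAE among n non-binders, so larger
screens use stricter cutoffs.  The comparison is inclusive (a call exactly
at the threshold passes).  Refit these constants for a different non-binder
pool with :mod:`slimpae.thresholds`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .errors import (
    ChainCountError,
    DimensionMismatchError,
    DomainError,
    MethodMismatchError,
)
from .io_afmodel import PredictionRecord, ResidueProfile
from .scoring import min_inter_pae_profile

__all__ = [
    "MotifCall",
    "call_motif_minipae",
    "call_motif_alphaslim",
    "adaptive_threshold",
    "filter_calls",
    "attach_sequences",
    "DEFAULT_THRESHOLD_PARAMS",
]

#: Power-law constants (a, b, c) of the published adaptive MiniPAE threshold.
DEFAULT_THRESHOLD_PARAMS = (30.29, 0.2803, -3.82)

#: Default half-width (A) of the PAE band around the minimum that defines
#: the motif window.
DEFAULT_DELTA = 3.0


@dataclass(frozen=True)
class MotifCall:
    """A localized SLiM candidate.

    ``start``/``end``/``anchor`` are 1-based inclusive positions within the
    candidate chain; ``score`` is the MiniPAE (A, lower better) for
    ``method='minipae'`` or the maximum AlphaSLiM value (higher better) for
    ``method='alphaslim'``.  ``passed`` records the outcome of threshold
    filtering, None before filtering.
    """

    record_id: str
    chain: str
    start: int
    end: int
    anchor: int
    score: float
    method: str = "minipae"
    sequence: str | None = None
    passed: bool | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.anchor <= self.end:
            raise DimensionMismatchError(
                f"require 1 <= start <= anchor <= end, got "
                f"({self.start}, {self.anchor}, {self.end})"
            )
        if self.method not in ("minipae", "alphaslim"):
            raise MethodMismatchError(f"unknown method {self.method!r}")
        if self.sequence is not None and len(self.sequence) != self.width:
            raise DimensionMismatchError(
                f"sequence length {len(self.sequence)} != window width "
                f"{self.width}"
            )

    @property
    def width(self) -> int:
        return self.end - self.start + 1


def _band_run(values: np.ndarray, anchor0: int, ceiling: float) -> tuple[int, int]:
    """Maximal contiguous 0-based [lo, hi] around anchor0 with values <= ceiling."""
    lo = anchor0
    while lo > 0 and values[lo - 1] <= ceiling:
        lo -= 1
    hi = anchor0
    while hi < len(values) - 1 and values[hi + 1] <= ceiling:
        hi += 1
    return lo, hi


def call_motif_minipae(
    record: PredictionRecord,
    candidate_chain: str | None = None,
    delta: float = DEFAULT_DELTA,
    all_islands: bool = False,
) -> MotifCall | list[MotifCall]:
    """Localize the SLiM candidate from the inter-chain PAE map.

    The anchor is the arg-min of the candidate chain's per-residue minimum
    inter-chain PAE (first occurrence on ties); the motif is the maximal
    contiguous run containing the anchor with profile values <=
    MiniPAE + delta.  The call's score is the MiniPAE itself.

    With ``all_islands=True``, every maximal run of residues within the
    delta band is returned (ordered by position); the island containing the
    global minimum comes with the same coordinates as the default call.
    """
    part = record.partition
    if part.n_chains != 2:
        raise ChainCountError(
            f"motif calling requires exactly 2 chains, got {part.n_chains}"
        )
    if candidate_chain is None:
        candidate_chain = part.chain_ids[1]
    profile = min_inter_pae_profile(record, candidate_chain)
    values = profile.values
    anchor0 = int(np.argmin(values))  # first occurrence on ties
    minipae = float(values[anchor0])
    ceiling = minipae + delta

    if not all_islands:
        lo, hi = _band_run(values, anchor0, ceiling)
        return MotifCall(
            record_id=record.record_id,
            chain=candidate_chain,
            start=lo + 1,
            end=hi + 1,
            anchor=anchor0 + 1,
            score=minipae,
            method="minipae",
        )

    calls: list[MotifCall] = []
    in_band = values <= ceiling
    i = 0
    n = len(values)
    while i < n:
        if in_band[i]:
            j = i
            while j + 1 < n and in_band[j + 1]:
                j += 1
            island = values[i : j + 1]
            a0 = i + int(np.argmin(island))
            calls.append(
                MotifCall(
                    record_id=record.record_id,
                    chain=candidate_chain,
                    start=i + 1,
                    end=j + 1,
                    anchor=a0 + 1,
                    score=float(island.min()),
                    method="minipae",
                )
            )
            i = j + 1
        else:
            i += 1
    return calls


def call_motif_alphaslim(
    profile: ResidueProfile, record_id: str = ""
) -> list[MotifCall]:
    """Decompose an AlphaSLiM profile into motif calls.

    One call per maximal contiguous run of strictly positive values, scored
    by the run's maximum (anchor at the maximum, first occurrence on ties);
    returned sorted by score descending.  No positive residue -> empty list.
    """
    if profile.kind != "alphaslim":
        raise MethodMismatchError(
            f"expected an alphaslim profile, got kind {profile.kind!r}"
        )
    values = profile.values
    calls: list[MotifCall] = []
    n = len(values)
    i = 0
    while i < n:
        if values[i] > 0:
            j = i
            while j + 1 < n and values[j + 1] > 0:
                j += 1
            run = values[i : j + 1]
            a0 = i + int(np.argmax(run))
            calls.append(
                MotifCall(
                    record_id=record_id,
                    chain=profile.chain,
                    start=i + 1,
                    end=j + 1,
                    anchor=a0 + 1,
                    score=float(run.max()),
                    method="alphaslim",
                )
            )
            i = j + 1
        else:
            i += 1
    calls.sort(key=lambda c: -c.score)
    return calls


def adaptive_threshold(
    n: int, params: tuple[float, float, float] = DEFAULT_THRESHOLD_PARAMS
) -> float:
    """Screen-size-adaptive MiniPAE cutoff a*n^-b + c (A).

    ``n`` is the number of candidate predictions in the screen.  Strictly
    decreasing in n: screening many candidates demands a stricter cutoff
    because the minimum score among many non-binders drifts low by chance.
    """
    if n < 1:
        raise DomainError(f"screen size n must be >= 1, got {n}")
    a, b, c = params
    return a * float(n) ** (-b) + c


def filter_calls(
    calls: Sequence[MotifCall],
    n: int | None = None,
    override_threshold: float | None = None,
    params: tuple[float, float, float] = DEFAULT_THRESHOLD_PARAMS,
) -> list[MotifCall]:
    """Annotate calls against the adaptive threshold and keep the passes.

    The cutoff is ``override_threshold`` when given, else
    ``adaptive_threshold(n)``.  A call passes when score <= cutoff
    (inclusive).  All input calls are re-emitted with ``passed`` set; the
    returned list holds only the passing calls in their original order.
    Without an override, all calls must carry method ``minipae`` (the
    adaptive threshold is calibrated on MiniPAE scores only).
    """
    calls = list(calls)
    if override_threshold is not None:
        cutoff = float(override_threshold)
    else:
        if n is None:
            raise DomainError("filter_calls needs n= or override_threshold=")
        methods = {c.method for c in calls}
        if methods - {"minipae"}:
            raise MethodMismatchError(
                "adaptive threshold applies to MiniPAE calls only; got "
                f"methods {sorted(methods)} (pass override_threshold= to "
                "filter other scores)"
            )
        cutoff = adaptive_threshold(n, params)
    annotated = [replace(c, passed=bool(c.score <= cutoff)) for c in calls]
    return [c for c in annotated if c.passed]


def attach_sequences(
    calls: Sequence[MotifCall], sequences: Mapping[str, str]
) -> list[MotifCall]:
    """Populate motif sequences by 1-based inclusive slicing of chain
    sequences.  Calls whose chain is absent from the map keep sequence=None.
    """
    out: list[MotifCall] = []
    for c in calls:
        seq = sequences.get(c.chain)
        if seq is None:
            out.append(c)
            continue
        if c.end > len(seq):
            raise DimensionMismatchError(
                f"call {c.start}-{c.end} exceeds chain {c.chain!r} sequence "
                f"of length {len(seq)}"
            )
        out.append(replace(c, sequence=seq[c.start - 1 : c.end]))
    return out
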