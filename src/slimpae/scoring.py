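"""Confidence metrics for SLiM-mediated binary complex predictions.

Implements the four computed metrics used to rank bait-candidate pairs:

* **Model Confidence** — ``MC = 0.2 * pTM + 0.8 * ipTM``, AlphaFold's global
  interface-weighted confidence.
* **MiniPAE** — the minimum predicted aligned error over all inter-chain
  residue pairs; a confident interface anywhere in the complex drives it
  low.  Lower is better.
* **per-residue minimum inter-chain PAE** — the per-residue track MiniPAE is
  the minimum of; used for motif localization.
* **AlphaSLiM** — ``N * (pLDDT_bound - pLDDT_unbound)`` per residue, where N
  counts interface interactions of that residue.  Highlights
  disorder-to-order transitions caused by binding.  The interaction count N
  is computed here as a heavy-atom contact count at a distance cutoff
  (default 4.0 A); externally computed interaction-profiler counts can be
  substituted via :class:`ContactCounts`.

Two normalization schemes put heterogeneous metrics on a comparable 0-1
axis: direct division by the maximum (AlphaSLiM, BSA) and an inverse-affine
form for lower-is-better scores (MiniPAE, MinD).  The inverse form is
implemented exactly as printed in its source even though the best score maps
to ``(inv_max - inv_min)/inv_max`` rather than 1 — see ``normalize_inverse``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import gemmi
import numpy as np

from .errors import (
    ChainCountError,
    ChainLookupError,
    DegenerateInputError,
    DimensionMismatchError,
    DomainError,
    ScoreParseError,
)
from .io_afmodel import ChainPartition, PredictionRecord, ResidueProfile

__all__ = [
    "MetricValue",
    "ContactCounts",
    "ScoredPair",
    "model_confidence",
    "mini_pae",
    "min_inter_pae_profile",
    "alphaslim_profile",
    "contact_counts",
    "normalize_direct",
    "normalize_inverse",
    "score_pair",
]

#: Metrics computed by this module.
COMPUTED_METRICS = ("MC", "MiniPAE", "AlphaSLiM_max")
#: Metrics accepted only as pre-computed (ingested) values.
INGESTED_METRICS = ("MinD", "avg_model", "interface_area", "dG", "bsa_max")


@dataclass(frozen=True)
class MetricValue:
    """One named score for a prediction; ``derived`` is False for values
    ingested from external tools (MinD, average-model, PISA energies)."""

    name: str
    value: float
    derived: bool = True

    def __post_init__(self) -> None:
        if self.name not in COMPUTED_METRICS + INGESTED_METRICS:
            raise ScoreParseError(f"unknown metric name {self.name!r}")
        if self.name in INGESTED_METRICS and self.derived:
            raise ScoreParseError(
                f"{self.name} is ingest-only; derived must be False"
            )
        if self.name == "MC" and not 0.0 <= self.value <= 1.0:
            raise DomainError(f"MC={self.value} outside [0, 1]")
        if self.name == "MiniPAE" and self.value < 0:
            raise DomainError(f"MiniPAE={self.value} negative")


@dataclass
class ContactCounts:
    """Per-residue interface interaction counts N for the candidate chain."""

    chain: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.ndim != 1:
            raise DimensionMismatchError("contact counts must be 1-D")
        if np.any(self.counts < 0):
            raise DimensionMismatchError("contact counts must be non-negative")

    def __len__(self) -> int:
        return len(self.counts)


@dataclass
class ScoredPair:
    """All metrics for one bait-candidate prediction, plus a benchmark label."""

    pair_id: str
    bait_id: str
    candidate_id: str
    metrics: dict[str, MetricValue] = field(default_factory=dict)
    label: str = "unknown"  # binder | non_binder | unknown

    def __post_init__(self) -> None:
        if self.label not in ("binder", "non_binder", "unknown"):
            raise DomainError(f"invalid label {self.label!r}")

    def value(self, name: str) -> float:
        return self.metrics[name].value


def model_confidence(ptm: float, iptm: float) -> float:
    """Model Confidence, MC = 0.2*pTM + 0.8*ipTM.

    Weights the interface term four times the global term, reflecting that
    binary-complex screening cares about the interface.
    """
    for name, v in (("ptm", ptm), ("iptm", iptm)):
        if not 0.0 <= float(v) <= 1.0:
            raise DomainError(f"{name}={v} outside [0, 1]")
    return 0.2 * float(ptm) + 0.8 * float(iptm)


def _inter_chain_mask(partition: ChainPartition) -> np.ndarray:
    if partition.n_chains != 2:
        raise ChainCountError(
            f"inter-chain scoring requires exactly 2 chains, got "
            f"{partition.n_chains}"
        )
    L = partition.total_length
    owner = np.zeros(L, dtype=int)
    owner[partition.block(partition.chain_ids[1])] = 1
    return owner[:, None] != owner[None, :]


def mini_pae(record: PredictionRecord) -> MetricValue:
    """Minimum PAE over all inter-chain residue pairs (both off-diagonal
    blocks of the asymmetric matrix).  Lower is better."""
    mask = _inter_chain_mask(record.partition)
    return MetricValue("MiniPAE", float(record.pae[mask].min()))


def mini_pae_argmin(record: PredictionRecord) -> tuple[int, int]:
    """0-based concatenated (row, column) of the inter-chain PAE minimum;
    first occurrence in row-major order on ties."""
    mask = _inter_chain_mask(record.partition)
    masked = np.where(mask, record.pae, np.inf)
    flat = int(np.argmin(masked))
    return flat // record.L, flat % record.L


def min_inter_pae_profile(record: PredictionRecord, chain: str) -> ResidueProfile:
    """Per-residue minimum inter-chain PAE for ``chain``.

    For residue r the value is the minimum over all PAE cells pairing r with
    any residue of the other chain, in both orientations (row r and
    column r).  The minimum of this profile equals MiniPAE.
    """
    part = record.partition
    other = part.other_chain(chain)  # validates two-chain + membership
    rows = part.block(chain)
    cols = part.block(other)
    by_row = record.pae[rows, cols].min(axis=1)
    by_col = record.pae[cols, rows].min(axis=0)
    return ResidueProfile(
        chain=chain, values=np.minimum(by_row, by_col), kind="min_inter_pae"
    )


def alphaslim_profile(
    bound_plddt: ResidueProfile,
    unbound_plddt: ResidueProfile,
    contacts: ContactCounts,
) -> ResidueProfile:
    """AlphaSLiM score per residue: N * (pLDDT_bound - pLDDT_unbound).

    ``bound_plddt`` comes from the binary-complex prediction,
    ``unbound_plddt`` from a monomer prediction of the candidate alone.
    Values can be negative where binding lowers confidence.
    """
    if not (bound_plddt.chain == unbound_plddt.chain == contacts.chain):
        raise DimensionMismatchError(
            "bound/unbound/contacts must refer to the same chain, got "
            f"{bound_plddt.chain!r}/{unbound_plddt.chain!r}/{contacts.chain!r}"
        )
    if not (len(bound_plddt) == len(unbound_plddt) == len(contacts)):
        raise DimensionMismatchError(
            f"length mismatch: bound {len(bound_plddt)}, unbound "
            f"{len(unbound_plddt)}, contacts {len(contacts)}"
        )
    values = contacts.counts * (bound_plddt.values - unbound_plddt.values)
    return ResidueProfile(chain=contacts.chain, values=values, kind="alphaslim")


def contact_counts(
    structure_path: str | Path,
    candidate_chain: str,
    cutoff: float = 4.0,
) -> ContactCounts:
    """Heavy-atom interface contact counts for each candidate-chain residue.

    ``counts[r]`` is the number of bait-chain heavy atoms within ``cutoff``
    (A) of any heavy atom of residue r.  This is a deterministic geometric
    stand-in for interaction-profiler counts; substitute externally computed
    counts by constructing :class:`ContactCounts` directly.
    """
    structure_path = Path(structure_path)
    try:
        st = gemmi.read_structure(str(structure_path))
    except (RuntimeError, ValueError) as exc:
        raise ScoreParseError(
            f"{structure_path}: cannot parse structure ({exc})"
        ) from exc
    if len(st) == 0:
        raise ScoreParseError(f"{structure_path}: structure has no models")
    model = st[0]
    chains = {ch.name: ch for ch in model}
    if candidate_chain not in chains:
        raise ChainLookupError(
            f"chain {candidate_chain!r} not in structure (has "
            f"{sorted(chains)})"
        )
    if len(chains) != 2:
        raise ChainCountError(
            f"contact counting requires exactly 2 chains, got {len(chains)}"
        )
    (bait_name,) = [name for name in chains if name != candidate_chain]

    def heavy_coords(residue) -> np.ndarray:
        pts = [
            (a.pos.x, a.pos.y, a.pos.z)
            for a in residue
            if a.element.name != "H"
        ]
        return np.asarray(pts, dtype=float)

    bait_atoms = [
        heavy_coords(res) for res in chains[bait_name] if not res.is_water()
    ]
    if not bait_atoms or all(len(a) == 0 for a in bait_atoms):
        raise ScoreParseError(f"{structure_path}: bait chain has no coordinates")
    bait_xyz = np.concatenate([a for a in bait_atoms if len(a)])

    cand_residues = [res for res in chains[candidate_chain] if not res.is_water()]
    counts = np.zeros(len(cand_residues), dtype=int)
    for i, res in enumerate(cand_residues):
        xyz = heavy_coords(res)
        if len(xyz) == 0:
            continue
        d2 = ((bait_xyz[:, None, :] - xyz[None, :, :]) ** 2).sum(axis=2)
        # bait atoms within cutoff of ANY heavy atom of this residue
        counts[i] = int((d2.min(axis=1) <= cutoff**2).sum())
    return ContactCounts(chain=candidate_chain, counts=counts)


def normalize_direct(values: Sequence[float]) -> np.ndarray:
    """Scale non-negative scores by the dataset maximum (max maps to 1)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise DegenerateInputError("cannot normalize an empty dataset")
    if np.any(v < 0):
        raise DomainError("direct normalization requires non-negative values")
    vmax = float(v.max())
    if vmax <= 0:
        raise DegenerateInputError("all values are zero; maximum undefined")
    return v / vmax


def normalize_inverse(values: Sequence[float]) -> np.ndarray:
    """Inverse-affine normalization for lower-is-better scores.

    With ``inv = 1/score``:  ``norm = (inv - inv_min) / inv_max``.

    Note the denominator is ``inv_max``, not ``inv_max - inv_min``: the best
    (lowest) original score maps to ``(inv_max - inv_min)/inv_max``, not 1,
    and the worst maps to 0.  This asymmetry is intentional and kept as
    defined by the metric's source.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise DegenerateInputError(
            "inverse normalization needs at least two values"
        )
    if np.any(v <= 0):
        raise DomainError("inverse normalization requires strictly positive values")
    inv = 1.0 / v
    return (inv - inv.min()) / inv.max()


def score_pair(
    record: PredictionRecord,
    monomer_plddt: ResidueProfile | None = None,
    structure_path: str | Path | None = None,
    candidate_chain: str | None = None,
    contact_cutoff: float = 4.0,
    contacts: ContactCounts | None = None,
    ingested: Mapping[str, float] | None = None,
    label: str = "unknown",
) -> ScoredPair:
    """Bundle all metrics for one bait-candidate prediction.

    MC and MiniPAE are always computed.  AlphaSLiM_max additionally requires
    the candidate's monomer (unbound) pLDDT profile and either a structure
    file or pre-computed :class:`ContactCounts`; when those are absent the
    metric is absent (not zero).  ``ingested`` attaches externally computed
    scores (MinD, avg_model, interface_area, dG) with ``derived=False``.

    The candidate chain defaults to the second chain of the partition (bait
    first, candidate second, matching the generator's convention).
    """
    part = record.partition
    if candidate_chain is None:
        if part.n_chains != 2:
            raise ChainCountError(
                f"scoring requires exactly 2 chains, got {part.n_chains}"
            )
        candidate_chain = part.chain_ids[1]
    bait_chain = part.other_chain(candidate_chain)

    metrics: dict[str, MetricValue] = {
        "MC": MetricValue("MC", model_confidence(record.ptm, record.iptm)),
        "MiniPAE": mini_pae(record),
    }

    if monomer_plddt is not None:
        if contacts is None:
            if structure_path is None:
                raise DimensionMismatchError(
                    "AlphaSLiM needs contact counts: pass structure_path= or "
                    "contacts="
                )
            contacts = contact_counts(
                structure_path, candidate_chain, cutoff=contact_cutoff
            )
        profile = alphaslim_profile(
            record.chain_plddt(candidate_chain), monomer_plddt, contacts
        )
        metrics["AlphaSLiM_max"] = MetricValue(
            "AlphaSLiM_max", float(profile.values.max())
        )

    if ingested:
        for name, value in ingested.items():
            if name not in INGESTED_METRICS:
                raise ScoreParseError(
                    f"{name!r} is not an ingestable metric "
                    f"(one of {INGESTED_METRICS})"
                )
            metrics[name] = MetricValue(name, float(value), derived=False)

    return ScoredPair(
        pair_id=record.record_id,
        bait_id=bait_chain,
        candidate_id=candidate_chain,
        metrics=metrics,
        label=label,
    )
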