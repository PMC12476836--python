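"""Synthetic AlphaFold-style prediction bundles with known ground truth.

Real inputs to this package are AlphaFold binary-complex outputs — hundreds
of megabytes per screen.  This module generates statistically controlled
stand-ins at any size: a two-chain prediction with a planted low-PAE "motif
stripe" (binder) or a uniformly high inter-chain PAE (non-binder), written
in either supported dialect so the readers, scorers and motif callers can
be exercised end to end with no download.

A binder fixture plants, for a chosen motif interval of the candidate
chain, inter-chain PAE values at ``stripe_pae`` against a ``background_pae``
elsewhere, optional Gaussian noise on every cell, and a pLDDT boost on the
motif residues emulating a disorder-to-order transition.  The companion
CA-only PDB places motif residues within contact distance of the bait so
geometric contact counting agrees with the planted stripe.  Everything is
deterministic from the spec's seed.

The fixtures emulate the statistical signature of SLiM predictions (a
confident interface patch inside an otherwise uncertain complex), not
AlphaFold's error covariance; see the package docs for what that does and
does not validate.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import gemmi
import json
import numpy as np

from .errors import FixtureSpecError
from .io_afmodel import PAE_RANGE, ResidueProfile

__all__ = [
    "FixtureSpec",
    "DistributionSpec",
    "make_prediction_bundle",
    "make_score_pools",
    "make_monomer_plddt",
]

_BAIT_PLDDT = 85.0  # folded bait chain
_INTRA_PAE = 1.5  # confident intra-chain geometry


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic binary-complex prediction.

    ``motif_start`` is 1-based within the candidate chain; ``motif_start``
    and ``motif_width`` are None for non-binder fixtures (no stripe).  The
    default geometry — a 120-residue folded bait and an 80-residue
    disordered candidate carrying an 8-residue motif — mirrors a typical
    SLiM screen pair; stripe/background PAE of 2 and 25 A reflect a
    confident interface patch against an otherwise unconfident complex.
    """

    record_id: str = "fixture"
    bait_len: int = 120
    candidate_len: int = 80
    motif_start: int | None = 30
    motif_width: int | None = 8
    stripe_pae: float = 2.0
    background_pae: float = 25.0
    pae_noise_sd: float = 0.0
    plddt_base: float = 40.0
    plddt_boost: float = 30.0
    ptm: float = 0.6
    iptm: float = 0.7
    seed: int = 0
    dialect: str = "af2_colabfold"
    bait_chain: str = "A"
    candidate_chain: str = "B"

    def __post_init__(self) -> None:
        if self.dialect not in ("af2_colabfold", "af3_server"):
            raise FixtureSpecError(f"unknown dialect {self.dialect!r}")
        if self.bait_len < 1 or self.candidate_len < 1:
            raise FixtureSpecError("chain lengths must be >= 1")
        if (self.motif_start is None) != (self.motif_width is None):
            raise FixtureSpecError(
                "motif_start and motif_width must be both set or both None"
            )
        if self.is_binder:
            if self.motif_width < 1 or self.motif_start < 1:
                raise FixtureSpecError("motif interval must be positive")
            if self.motif_start + self.motif_width - 1 > self.candidate_len:
                raise FixtureSpecError(
                    f"motif {self.motif_start}+{self.motif_width} exceeds "
                    f"candidate chain of length {self.candidate_len}"
                )
            if not self.stripe_pae < self.background_pae:
                raise FixtureSpecError(
                    "binder fixtures require stripe_pae < background_pae"
                )

    @property
    def is_binder(self) -> bool:
        return self.motif_start is not None

    @property
    def motif_interval(self) -> tuple[int, int] | None:
        """1-based inclusive (start, end) of the planted motif, or None."""
        if not self.is_binder:
            return None
        return self.motif_start, self.motif_start + self.motif_width - 1

    @property
    def L(self) -> int:
        return self.bait_len + self.candidate_len


def _rng(spec: FixtureSpec, stream: int) -> np.random.Generator:
    # fixed sub-stream keys so e.g. the monomer track reuses the bound
    # candidate's base-pLDDT noise realization
    return np.random.default_rng([spec.seed & 0x7FFFFFFF, stream])


def _motif_mask(spec: FixtureSpec) -> np.ndarray:
    mask = np.zeros(spec.candidate_len, dtype=bool)
    if spec.is_binder:
        start, end = spec.motif_interval
        mask[start - 1 : end] = True
    return mask


def _candidate_base_plddt(spec: FixtureSpec) -> np.ndarray:
    noise = _rng(spec, 1).normal(0.0, spec.pae_noise_sd, spec.candidate_len)
    return np.clip(spec.plddt_base + noise, 0.0, 100.0)


def _build_arrays(spec: FixtureSpec) -> tuple[np.ndarray, np.ndarray]:
    """(PAE matrix, pLDDT vector) on the concatenated bait+candidate axis."""
    L, nb = spec.L, spec.bait_len
    pae = np.full((L, L), float(spec.background_pae))
    pae[:nb, :nb] = _INTRA_PAE
    pae[nb:, nb:] = _INTRA_PAE
    if spec.is_binder:
        start, end = spec.motif_interval
        rows = slice(nb + start - 1, nb + end)
        pae[rows, :nb] = spec.stripe_pae
        pae[:nb, rows] = spec.stripe_pae
    if spec.pae_noise_sd > 0:
        pae = pae + _rng(spec, 0).normal(0.0, spec.pae_noise_sd, (L, L))
    pae = np.clip(pae, *PAE_RANGE)

    bait_plddt = np.clip(
        _BAIT_PLDDT + _rng(spec, 2).normal(0.0, spec.pae_noise_sd, nb),
        0.0,
        100.0,
    )
    cand_plddt = _candidate_base_plddt(spec).copy()
    cand_plddt[_motif_mask(spec)] += spec.plddt_boost
    plddt = np.concatenate([bait_plddt, np.clip(cand_plddt, 0.0, 100.0)])
    return pae, plddt


def _build_structure(spec: FixtureSpec) -> gemmi.Structure:
    """CA-only two-chain model: bait along the x axis, candidate on a
    parallel line 30 A away except motif residues pulled to 3 A (inside the
    4 A contact cutoff of a bait CA at the same x)."""
    st = gemmi.Structure()
    st.name = spec.record_id
    model = gemmi.Model("1")
    mask = _motif_mask(spec)

    def add_chain(name: str, n: int, y_of) -> None:
        chain = gemmi.Chain(name)
        for i in range(n):
            res = gemmi.Residue()
            res.name = "ALA"
            res.seqid = gemmi.SeqId(i + 1, " ")
            atom = gemmi.Atom()
            atom.name = "CA"
            atom.element = gemmi.Element("C")
            atom.pos = gemmi.Position(3.8 * i, y_of(i), 0.0)
            res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)

    add_chain(spec.bait_chain, spec.bait_len, lambda i: 0.0)
    add_chain(
        spec.candidate_chain,
        spec.candidate_len,
        lambda i: 3.0 if mask[i] else 30.0,
    )
    st.add_model(model)
    st.setup_entities()
    return st


def make_prediction_bundle(spec: FixtureSpec, out_dir: str | Path) -> dict:
    """Write one synthetic prediction bundle readable by the package readers.

    For ``af2_colabfold``: a ColabFold-style score JSON plus a CA-only
    two-chain PDB.  For ``af3_server``: an AF3-server-style directory with
    full-data and summary-confidences JSON (one token and one atom per
    residue) plus the same PDB.  Deterministic: the same spec produces
    byte-identical files.

    Returns a manifest dict with the written paths, chain layout and the
    planted motif interval (None for non-binders).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pae, plddt = _build_arrays(spec)
    # 2-decimal rounding mirrors AF output files and keeps them compact
    pae_out = [[round(float(v), 2) for v in row] for row in pae]
    plddt_out = [round(float(v), 2) for v in plddt]

    structure_path = out_dir / f"{spec.record_id}_unrelaxed_rank_001.pdb"
    _build_structure(spec).write_pdb(str(structure_path))

    manifest = {
        "record_id": spec.record_id,
        "dialect": spec.dialect,
        "structure_path": structure_path,
        "chain_ids": (spec.bait_chain, spec.candidate_chain),
        "chain_lengths": (spec.bait_len, spec.candidate_len),
        "motif_interval": spec.motif_interval,
        "is_binder": spec.is_binder,
    }

    if spec.dialect == "af2_colabfold":
        score_path = out_dir / f"{spec.record_id}_scores_rank_001.json"
        score_path.write_text(
            json.dumps(
                {
                    "pae": pae_out,
                    "plddt": plddt_out,
                    "ptm": spec.ptm,
                    "iptm": spec.iptm,
                    "max_pae": PAE_RANGE[1],
                },
                separators=(",", ":"),
            )
        )
        manifest["score_path"] = score_path
        return manifest

    bundle_dir = out_dir / spec.record_id
    bundle_dir.mkdir(exist_ok=True)
    chains = [spec.bait_chain] * spec.bait_len + [
        spec.candidate_chain
    ] * spec.candidate_len
    res_ids = list(range(1, spec.bait_len + 1)) + list(
        range(1, spec.candidate_len + 1)
    )
    full = {
        "pae": pae_out,
        "token_chain_ids": chains,
        "token_res_ids": res_ids,
        "atom_plddts": plddt_out,
        "atom_chain_ids": chains,
        "atom_res_ids": res_ids,
    }
    summary = {"ptm": spec.ptm, "iptm": spec.iptm}
    full_path = bundle_dir / f"fold_{spec.record_id}_full_data_0.json"
    summary_path = bundle_dir / f"fold_{spec.record_id}_summary_confidences_0.json"
    full_path.write_text(json.dumps(full, separators=(",", ":")))
    summary_path.write_text(json.dumps(summary, separators=(",", ":")))
    manifest["bundle_path"] = bundle_dir
    return manifest


def make_monomer_plddt(spec: FixtureSpec) -> ResidueProfile:
    """Unbound (monomer) pLDDT track of the candidate chain.

    Reuses the bound prediction's base-pLDDT noise realization without the
    motif boost, so the bound-unbound difference equals the boost exactly
    on the motif and zero elsewhere.
    """
    return ResidueProfile(
        chain=spec.candidate_chain,
        values=_candidate_base_plddt(spec),
        kind="custom",
    )


@dataclass(frozen=True)
class DistributionSpec:
    """A 1-D score distribution: family in {normal, exponential, uniform,
    point}; ``loc``/``scale`` are mean/sd (normal), offset/mean (shifted
    exponential), low/width (uniform) or value/ignored (point)."""

    family: str
    loc: float
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.family not in ("normal", "exponential", "uniform", "point"):
            raise FixtureSpecError(f"unknown distribution family {self.family!r}")
        if self.family != "point" and self.scale < 0:
            raise FixtureSpecError("scale must be non-negative")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.family == "normal":
            draws = rng.normal(self.loc, self.scale, n)
        elif self.family == "exponential":
            draws = self.loc + rng.exponential(self.scale, n)
        elif self.family == "uniform":
            draws = rng.uniform(self.loc, self.loc + self.scale, n)
        else:
            draws = np.full(n, self.loc)
        return np.clip(draws, *PAE_RANGE)


def make_score_pools(
    n_pos: int,
    n_neg: int,
    pos_dist: DistributionSpec | Sequence = DistributionSpec("normal", 3.0, 1.0),
    neg_dist: DistributionSpec | Sequence = DistributionSpec("normal", 20.0, 4.0),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Labeled MiniPAE-like score pools, clipped to the PAE output range.

    Defaults emulate a separated screen: binder minima a few Angstrom
    (confident interfaces), non-binders high.  Accepts
    :class:`DistributionSpec` or plain ``(family, loc, scale)`` tuples.
    Returns (positive scores, negative scores).
    """
    if not isinstance(pos_dist, DistributionSpec):
        pos_dist = DistributionSpec(*pos_dist)
    if not isinstance(neg_dist, DistributionSpec):
        neg_dist = DistributionSpec(*neg_dist)
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 17])
    return pos_dist.sample(n_pos, rng), neg_dist.sample(n_neg, rng)
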