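"""Readers and writers for AlphaFold binary-complex confidence output.

Two dialects are supported and normalised into a single
:class:`PredictionRecord`:

* ``af2_colabfold`` — ColabFold per-model score JSON (``pae``/
  ``predicted_aligned_error``, ``plddt``, ``ptm``, ``iptm``).  The score file
  carries no chain boundaries, so the caller must supply explicit chain
  lengths or the matching structure file (PDB/mmCIF) from which the partition
  is read.
* ``af3_server`` — the AlphaFold3 server bundle: a full-data JSON with the
  token-level PAE matrix and atom-level pLDDT, plus a summary-confidences
  JSON with pTM/ipTM.  Atom pLDDTs are averaged per residue and the token PAE
  is reduced to a residue-by-residue matrix (minimum over token pairs, which
  is the identity for standard one-token-per-residue proteins).

Coordinates are 1-based inclusive in every user-facing structure; the
concatenated residue axis used internally is 0-based.
"""

from __future__ import annotations

import json
import re
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

from .errors import (
    BundleIncompleteError,
    ChainLookupError,
    DimensionMismatchError,
    MissingPartitionError,
    ScoreParseError,
)

__all__ = [
    "ChainPartition",
    "PredictionRecord",
    "ResidueProfile",
    "read_colabfold_record",
    "read_af3_record",
    "write_motif_table",
    "write_score_table",
    "partition_from_structure",
]

#: Practical output range of AlphaFold PAE values in Angstrom.
PAE_RANGE = (0.2, 31.75)

MOTIF_TABLE_COLUMNS = (
    "record_id",
    "candidate_chain",
    "motif_start",
    "motif_end",
    "motif_sequence",
    "minipae",
    "passed_threshold",
)


@dataclass(frozen=True)
class ChainPartition:
    """Partition of the concatenated residue axis into labelled chains.

    ``offsets[k]`` is the 0-based start of chain ``k`` on the concatenated
    axis; within-chain positions are 1-based in the public API.
    """

    chain_ids: tuple[str, ...]
    chain_lengths: tuple[int, ...]
    offsets: tuple[int, ...] = field(init=False)

    def __post_init__(self) -> None:
        if len(self.chain_ids) != len(self.chain_lengths):
            raise DimensionMismatchError(
                f"{len(self.chain_ids)} chain ids vs "
                f"{len(self.chain_lengths)} chain lengths"
            )
        if len(self.chain_ids) != len(set(self.chain_ids)):
            raise DimensionMismatchError(f"duplicate chain ids: {self.chain_ids}")
        if any(n <= 0 for n in self.chain_lengths):
            raise DimensionMismatchError(
                f"non-positive chain length in {self.chain_lengths}"
            )
        object.__setattr__(
            self,
            "offsets",
            tuple(int(x) for x in np.concatenate([[0], np.cumsum(self.chain_lengths)[:-1]])),
        )

    @property
    def total_length(self) -> int:
        return int(sum(self.chain_lengths))

    @property
    def n_chains(self) -> int:
        return len(self.chain_ids)

    def chain_index(self, chain: str) -> int:
        try:
            return self.chain_ids.index(chain)
        except ValueError:
            raise ChainLookupError(
                f"chain {chain!r} not in partition {self.chain_ids}"
            ) from None

    def block(self, chain: str) -> slice:
        """Slice of the concatenated axis covered by ``chain``."""
        k = self.chain_index(chain)
        return slice(self.offsets[k], self.offsets[k] + self.chain_lengths[k])

    def to_concat(self, chain: str, pos: int) -> int:
        """(chain, 1-based position) -> 0-based concatenated index."""
        k = self.chain_index(chain)
        if not 1 <= pos <= self.chain_lengths[k]:
            raise DimensionMismatchError(
                f"position {pos} outside chain {chain!r} of length "
                f"{self.chain_lengths[k]}"
            )
        return self.offsets[k] + pos - 1

    def from_concat(self, index: int) -> tuple[str, int]:
        """0-based concatenated index -> (chain, 1-based position)."""
        if not 0 <= index < self.total_length:
            raise DimensionMismatchError(
                f"index {index} outside concatenated axis of length "
                f"{self.total_length}"
            )
        for cid, off, n in zip(self.chain_ids, self.offsets, self.chain_lengths):
            if off <= index < off + n:
                return cid, index - off + 1
        raise AssertionError("unreachable: partition covers the axis")

    def other_chain(self, chain: str) -> str:
        """The partner chain label in a two-chain partition."""
        from .errors import ChainCountError

        if self.n_chains != 2:
            raise ChainCountError(
                f"expected exactly 2 chains, got {self.n_chains}"
            )
        k = self.chain_index(chain)
        return self.chain_ids[1 - k]


@dataclass
class PredictionRecord:
    """One parsed AlphaFold binary-complex model, dialect-neutral.

    The PAE matrix follows the AF convention: entry (i, j) is the expected
    position error (A) of residue j when the model is aligned on residue i.
    The matrix is kept asymmetric as emitted.
    """

    record_id: str
    partition: ChainPartition
    pae: np.ndarray
    plddt: np.ndarray
    ptm: float
    iptm: float
    max_pae: float = 31.75
    dialect: str = "af2_colabfold"
    model_rank: int = 1

    def __post_init__(self) -> None:
        self.pae = np.asarray(self.pae, dtype=float)
        self.plddt = np.asarray(self.plddt, dtype=float)
        L = self.partition.total_length
        if self.pae.ndim != 2 or self.pae.shape[0] != self.pae.shape[1]:
            raise DimensionMismatchError(f"PAE must be square, got {self.pae.shape}")
        if self.pae.shape[0] != L:
            raise DimensionMismatchError(
                f"chain lengths sum to {L} but PAE is {self.pae.shape[0]}x"
                f"{self.pae.shape[1]}"
            )
        if self.plddt.shape != (L,):
            raise DimensionMismatchError(
                f"pLDDT length {self.plddt.shape} does not match L={L}"
            )
        if np.any(self.pae < 0) or np.any(self.pae > self.max_pae + 1e-9):
            raise DimensionMismatchError(
                f"PAE entries outside [0, {self.max_pae}]"
            )
        if np.any(self.plddt < 0) or np.any(self.plddt > 100):
            raise DimensionMismatchError("pLDDT entries outside [0, 100]")
        for name, v in (("ptm", self.ptm), ("iptm", self.iptm)):
            if not 0.0 <= float(v) <= 1.0:
                raise DimensionMismatchError(f"{name}={v} outside [0, 1]")

    @property
    def L(self) -> int:
        return self.partition.total_length

    def chain_plddt(self, chain: str) -> "ResidueProfile":
        """Per-residue pLDDT of one chain as a profile."""
        return ResidueProfile(
            chain=chain, values=self.plddt[self.partition.block(chain)].copy(),
            kind="custom",
        )


@dataclass
class ResidueProfile:
    """One number per residue of a single chain.

    ``kind`` records what the values are: ``min_inter_pae`` (A),
    ``delta_plddt``, ``alphaslim``, ``bsa`` (A^2, ingested) or ``custom``.
    """

    chain: str
    values: np.ndarray
    kind: str = "custom"

    VALID_KINDS = ("min_inter_pae", "delta_plddt", "alphaslim", "bsa", "custom")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise DimensionMismatchError("profile values must be 1-D")
        if self.kind not in self.VALID_KINDS:
            raise ScoreParseError(f"unknown profile kind {self.kind!r}")
        if self.kind == "alphaslim" and not np.all(np.isfinite(self.values)):
            raise DimensionMismatchError("alphaslim profile must be finite")

    def __len__(self) -> int:
        return len(self.values)


# ---------------------------------------------------------------------------
# ColabFold (AF2) dialect
# ---------------------------------------------------------------------------

_RANK_RE = re.compile(r"rank[_.]?(\d+)", re.IGNORECASE)

# key aliases seen across ColabFold versions
_PAE_KEYS = ("pae", "predicted_aligned_error")
_PLDDT_KEYS = ("plddt",)
_PTM_KEYS = ("ptm",)
_IPTM_KEYS = ("iptm",)


def _first_key(data: dict, keys: Sequence[str], path) -> object:
    for k in keys:
        if k in data:
            return data[k]
    raise ScoreParseError(f"{path}: missing key {keys[0]!r}")


def read_colabfold_record(
    score_path: str | Path,
    chain_lengths: Sequence[int] | None = None,
    structure_path: str | Path | None = None,
    chain_ids: Sequence[str] | None = None,
    record_id: str | None = None,
) -> PredictionRecord:
    """Read one ColabFold score JSON into a :class:`PredictionRecord`.

    ColabFold score files do not encode complex boundaries, so exactly one of
    ``chain_lengths`` or ``structure_path`` must identify the chain
    partition.  ``model_rank`` is parsed from a ``rank_NNN`` token in the
    file name when present, else 1.
    """
    score_path = Path(score_path)
    try:
        data = json.loads(score_path.read_text())
    except json.JSONDecodeError as exc:
        raise ScoreParseError(f"{score_path}: invalid JSON ({exc})") from exc

    pae = np.asarray(_first_key(data, _PAE_KEYS, score_path), dtype=float)
    plddt = np.asarray(_first_key(data, _PLDDT_KEYS, score_path), dtype=float)
    ptm = float(_first_key(data, _PTM_KEYS, score_path))
    iptm = float(_first_key(data, _IPTM_KEYS, score_path))
    max_pae = float(data.get("max_pae", PAE_RANGE[1]))

    if chain_lengths is not None and structure_path is not None:
        raise MissingPartitionError(
            "supply chain_lengths or structure_path, not both"
        )
    if chain_lengths is not None:
        ids = tuple(chain_ids) if chain_ids is not None else _default_chain_ids(
            len(chain_lengths)
        )
        partition = ChainPartition(ids, tuple(int(n) for n in chain_lengths))
    elif structure_path is not None:
        partition = partition_from_structure(structure_path)
    else:
        raise MissingPartitionError(
            f"{score_path}: chain boundaries are not derivable from a "
            "ColabFold score file; pass chain_lengths= or structure_path="
        )

    if partition.total_length != pae.shape[0]:
        raise DimensionMismatchError(
            f"{score_path}: chain lengths sum to {partition.total_length} "
            f"but PAE is {pae.shape[0]}x{pae.shape[-1]}"
        )

    m = _RANK_RE.search(score_path.name)
    rank = int(m.group(1)) if m else 1
    rid = record_id if record_id is not None else _strip_score_suffix(score_path)
    return PredictionRecord(
        record_id=rid,
        partition=partition,
        pae=pae,
        plddt=plddt,
        ptm=ptm,
        iptm=iptm,
        max_pae=max_pae,
        dialect="af2_colabfold",
        model_rank=rank,
    )


def _strip_score_suffix(path: Path) -> str:
    name = path.stem
    for marker in ("_scores_rank", "_scores", "_score"):
        if marker in name:
            return name.split(marker)[0]
    return name


def _default_chain_ids(n: int) -> tuple[str, ...]:
    alphabet = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    if n > len(alphabet):
        raise DimensionMismatchError(f"too many chains ({n})")
    return tuple(alphabet[:n])


def partition_from_structure(structure_path: str | Path) -> ChainPartition:
    """Derive the chain partition from a PDB/mmCIF structure file."""
    structure_path = Path(structure_path)
    try:
        st = gemmi.read_structure(str(structure_path))
    except (RuntimeError, ValueError) as exc:
        raise ScoreParseError(f"{structure_path}: cannot parse structure ({exc})") from exc
    if len(st) == 0:
        raise ScoreParseError(f"{structure_path}: structure has no models")
    model = st[0]
    ids, lengths = [], []
    for chain in model:
        n = sum(1 for res in chain if not res.is_water())
        if n:
            ids.append(chain.name)
            lengths.append(n)
    if not ids:
        raise ScoreParseError(f"{structure_path}: no polymer chains found")
    return ChainPartition(tuple(ids), tuple(lengths))


# ---------------------------------------------------------------------------
# AF3 server dialect
# ---------------------------------------------------------------------------


def read_af3_record(
    bundle_path: str | Path, record_id: str | None = None
) -> PredictionRecord:
    """Read an AlphaFold3-server output bundle (directory or zip).

    Requires the full-data JSON (token PAE + chain ids, atom pLDDT + chain
    ids) and the summary-confidences JSON (pTM/ipTM).  Token PAE is reduced
    to residue level by taking, for each residue pair, the minimum over their
    token pairs; atom pLDDTs are averaged per residue.  The atom->residue
    mapping uses ``atom_res_ids`` when present, else one atom per residue in
    order.
    """
    bundle_path = Path(bundle_path)
    full, summary = _load_af3_bundle(bundle_path)

    for key in ("pae", "token_chain_ids", "atom_plddts", "atom_chain_ids"):
        if key not in full:
            raise BundleIncompleteError(
                f"{bundle_path}: full-data JSON missing {key!r}"
            )
    for key in ("ptm", "iptm"):
        if key not in summary:
            raise BundleIncompleteError(
                f"{bundle_path}: summary confidences missing {key!r}"
            )

    token_pae = np.asarray(full["pae"], dtype=float)
    token_chain = np.asarray(full["token_chain_ids"], dtype=str)
    if token_pae.shape[0] != token_chain.shape[0]:
        raise DimensionMismatchError(
            f"{bundle_path}: {token_pae.shape[0]} PAE tokens vs "
            f"{token_chain.shape[0]} token chain ids"
        )
    token_res = (
        np.asarray(full["token_res_ids"], dtype=int)
        if "token_res_ids" in full
        else _sequential_res_ids(token_chain)
    )

    atom_plddt = np.asarray(full["atom_plddts"], dtype=float)
    atom_chain = np.asarray(full["atom_chain_ids"], dtype=str)
    if atom_plddt.shape[0] != atom_chain.shape[0]:
        raise DimensionMismatchError(
            f"{bundle_path}: atom pLDDT / chain id arrays differ in length"
        )
    atom_res = (
        np.asarray(full["atom_res_ids"], dtype=int)
        if "atom_res_ids" in full
        else _sequential_res_ids(atom_chain)
    )

    # residue ordering follows the token axis (chains in emitted order)
    chain_order = list(dict.fromkeys(token_chain.tolist()))
    residues: list[tuple[str, int]] = list(
        dict.fromkeys(zip(token_chain.tolist(), token_res.tolist()))
    )
    res_index = {key: i for i, key in enumerate(residues)}
    lengths = tuple(
        sum(1 for c, _ in residues if c == cid) for cid in chain_order
    )
    partition = ChainPartition(tuple(chain_order), lengths)
    L = partition.total_length

    token_owner = np.array(
        [res_index[(c, r)] for c, r in zip(token_chain.tolist(), token_res.tolist())]
    )
    if token_owner.shape[0] == L:
        pae = token_pae  # one token per residue: identity mapping
    else:
        pae = np.full((L, L), np.inf)
        # minimum over token pairs: conservative toward detecting contacts
        np.minimum.at(pae, (token_owner[:, None], token_owner[None, :]), token_pae)

    plddt = np.zeros(L)
    counts = np.zeros(L)
    for p, c, r in zip(atom_plddt.tolist(), atom_chain.tolist(), atom_res.tolist()):
        key = (c, r)
        if key not in res_index:
            raise DimensionMismatchError(
                f"{bundle_path}: atom maps to residue {key} absent from the "
                "token axis"
            )
        plddt[res_index[key]] += p
        counts[res_index[key]] += 1
    if np.any(counts == 0):
        raise DimensionMismatchError(
            f"{bundle_path}: {int((counts == 0).sum())} residues have no atoms"
        )
    plddt /= counts

    rid = record_id if record_id is not None else bundle_path.stem
    return PredictionRecord(
        record_id=rid,
        partition=partition,
        pae=pae,
        plddt=plddt,
        ptm=float(summary["ptm"]),
        iptm=float(summary["iptm"]),
        max_pae=max(PAE_RANGE[1], float(np.max(pae))),
        dialect="af3_server",
        model_rank=1,
    )


def _sequential_res_ids(chain_ids: np.ndarray) -> np.ndarray:
    """Assign residue ids 1..n per chain assuming one entry per residue."""
    out = np.zeros(len(chain_ids), dtype=int)
    counters: dict[str, int] = {}
    for i, c in enumerate(chain_ids.tolist()):
        counters[c] = counters.get(c, 0) + 1
        out[i] = counters[c]
    return out


def _load_af3_bundle(bundle_path: Path) -> tuple[dict, dict]:
    if bundle_path.is_dir():
        full = _find_one(bundle_path, "full_data")
        summary = _find_one(bundle_path, "summary_confidences")
        return json.loads(full.read_text()), json.loads(summary.read_text())
    if bundle_path.suffix == ".zip":
        if not bundle_path.exists():
            raise BundleIncompleteError(f"{bundle_path}: no such bundle")
        with zipfile.ZipFile(bundle_path) as zf:
            names = zf.namelist()
            full_name = _match_one(names, "full_data", bundle_path)
            summary_name = _match_one(names, "summary_confidences", bundle_path)
            return (
                json.loads(zf.read(full_name)),
                json.loads(zf.read(summary_name)),
            )
    raise BundleIncompleteError(
        f"{bundle_path}: expected a directory or .zip bundle"
    )


def _find_one(directory: Path, token: str) -> Path:
    hits = sorted(p for p in directory.glob("*.json") if token in p.name)
    if not hits:
        raise BundleIncompleteError(f"{directory}: no *{token}*.json member")
    return hits[0]


def _match_one(names: Iterable[str], token: str, bundle: Path) -> str:
    hits = sorted(n for n in names if token in n and n.endswith(".json"))
    if not hits:
        raise BundleIncompleteError(f"{bundle}: no *{token}*.json member")
    return hits[0]


# ---------------------------------------------------------------------------
# Tabular output
# ---------------------------------------------------------------------------


def write_motif_table(calls: Sequence, path: str | Path) -> Path:
    """Write motif calls as a TSV table.

    Columns: record_id, candidate_chain, motif_start, motif_end (1-based
    inclusive), motif_sequence ("." when absent), minipae, passed_threshold.
    Rows are ordered by (record_id, motif_start).
    """
    path = Path(path)
    rows = sorted(calls, key=lambda c: (c.record_id, c.start))
    lines = ["\t".join(MOTIF_TABLE_COLUMNS)]
    for c in rows:
        seq = c.sequence if c.sequence else "."
        passed = "" if c.passed is None else str(bool(c.passed))
        lines.append(
            "\t".join(
                [
                    c.record_id,
                    c.chain,
                    str(c.start),
                    str(c.end),
                    seq,
                    format(float(c.score), "g"),
                    passed,
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def write_score_table(pairs: Sequence, path: str | Path) -> Path:
    """Write a CSV of ScoredPairs: record id, label and one column per metric."""
    import pandas as pd

    path = Path(path)
    metric_names: list[str] = []
    for p in pairs:
        for name in p.metrics:
            if name not in metric_names:
                metric_names.append(name)
    records = []
    for p in pairs:
        row: dict[str, object] = {
            "pair_id": p.pair_id,
            "bait_id": p.bait_id,
            "candidate_id": p.candidate_id,
            "label": p.label,
        }
        for name in metric_names:
            mv = p.metrics.get(name)
            row[name] = mv.value if mv is not None else np.nan
        records.append(row)
    df = pd.DataFrame.from_records(
        records, columns=["pair_id", "bait_id", "candidate_id", "label", *metric_names]
    )
    df.to_csv(path, index=False)
    return path
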