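"""Readers and writers for all external formats.

Cross-link and mono-link tables are tab-separated with fixed column names
(``protein_a, position_a, protein_b, position_b, q_value`` and
``protein, position, q_value``), the dialect of proxl-style exports.
Sequences are FASTA.  Bead models are written as PDB v3.3 pseudo-atom files
(one HETATM per bead) and localization densities as CCP4/MRC volumes, both
through gemmi.  Structured configuration is YAML.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from .representation import (
    Assembly,
    AssemblyTopology,
    Box,
    RigidTransform,
)

__all__ = [
    "CrossLinkRecord",
    "MonoLinkRecord",
    "read_fasta",
    "write_fasta",
    "read_crosslink_table",
    "write_crosslink_table",
    "read_monolink_table",
    "write_monolink_table",
    "read_bead_model",
    "write_bead_model",
    "write_density_map",
    "read_density_map",
    "load_config",
    "dump_config",
    "topology_from_config",
]

XL_COLUMNS = ["protein_a", "position_a", "protein_b", "position_b", "q_value"]
MONO_COLUMNS = ["protein", "position", "q_value"]

#: PDB chain identifiers available for bead models (62 = A-Z a-z 0-9).
_CHAIN_IDS = (
    "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"
)


@dataclass(frozen=True, order=True)
class CrossLinkRecord:
    """One unique distance restraint (UDR): a cross-linked residue pair.

    Records are order-normalized (endpoint ``a`` <= endpoint ``b``
    lexicographically, then by position) so that the same physical pair read
    in either orientation collapses to one UDR.
    """

    protein_a: str
    position_a: int
    protein_b: str
    position_b: int
    q_value: float = 0.0
    condition: str = ""

    def normalized(self) -> "CrossLinkRecord":
        a = (self.protein_a, self.position_a)
        b = (self.protein_b, self.position_b)
        if b < a:
            a, b = b, a
        return CrossLinkRecord(a[0], a[1], b[0], b[1], self.q_value, self.condition)

    @property
    def udr_key(self) -> tuple[str, int, str, int]:
        r = self.normalized()
        return (r.protein_a, r.position_a, r.protein_b, r.position_b)


@dataclass(frozen=True, order=True)
class MonoLinkRecord:
    """A singly modified (hydrolyzed cross-linker) residue."""

    protein: str
    position: int
    q_value: float = 0.0


def read_fasta(path) -> dict[str, str]:
    """Read sequences into a name -> one-letter-sequence map."""
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise ValueError(f"duplicate sequence name {record.id!r} in {path}")
        seq = str(record.seq).upper()
        if not seq:
            raise ValueError(f"empty sequence {record.id!r} in {path}")
        sequences[record.id] = seq
    return sequences


def write_fasta(sequences: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def read_crosslink_table(
    path,
    q_max: float = 0.01,
    sequences: dict[str, str] | None = None,
    condition: str = "",
) -> list[CrossLinkRecord]:
    """Read a TSV cross-link table, filter by q-value, deduplicate to UDRs.

    Returns the sorted list of unique distance restraints with
    ``q_value <= q_max``; each record is order-normalized first so swapped
    endpoint orientations collapse.  If ``sequences`` is given, every record
    is validated against it (known protein, position within range).
    """
    if not 0.0 <= q_max <= 1.0:
        raise ValueError(f"q_max must be in [0, 1], got {q_max}")
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in XL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    best: dict[tuple, CrossLinkRecord] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            rec = CrossLinkRecord(
                protein_a=str(row.protein_a),
                position_a=int(row.position_a),
                protein_b=str(row.protein_b),
                position_b=int(row.position_b),
                q_value=float(row.q_value),
                condition=condition,
            ).normalized()
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: malformed row at line {i + 2}: {exc}") from exc
        if rec.position_a < 1 or rec.position_b < 1:
            raise ValueError(f"{path}: non-positive position at line {i + 2}")
        if sequences is not None:
            for prot, pos in ((rec.protein_a, rec.position_a), (rec.protein_b, rec.position_b)):
                if prot not in sequences:
                    raise KeyError(f"{path}: unknown protein {prot!r} in record {rec}")
                if pos > len(sequences[prot]):
                    raise ValueError(
                        f"{path}: position {pos} beyond {prot!r} "
                        f"(length {len(sequences[prot])}) in record {rec}"
                    )
        if rec.q_value > q_max:
            continue
        key = rec.udr_key
        if key not in best or rec.q_value < best[key].q_value:
            best[key] = rec
    return sorted(best.values())


def write_crosslink_table(records, path) -> None:
    rows = [
        {
            "protein_a": r.protein_a,
            "position_a": r.position_a,
            "protein_b": r.protein_b,
            "position_b": r.position_b,
            "q_value": r.q_value,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=XL_COLUMNS).to_csv(path, sep="\t", index=False)


def read_monolink_table(
    path, q_max: float = 0.01, sequences: dict[str, str] | None = None
) -> list[MonoLinkRecord]:
    """Read a TSV mono-link table, filter by q-value, deduplicate."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in MONO_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    out: dict[tuple, MonoLinkRecord] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            rec = MonoLinkRecord(str(row.protein), int(row.position), float(row.q_value))
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: malformed row at line {i + 2}: {exc}") from exc
        if sequences is not None and rec.protein not in sequences:
            raise KeyError(f"{path}: unknown protein {rec.protein!r}")
        if rec.q_value > q_max:
            continue
        key = (rec.protein, rec.position)
        if key not in out or rec.q_value < out[key].q_value:
            out[key] = rec
    return sorted(out.values())


def write_monolink_table(records, path) -> None:
    rows = [
        {"protein": r.protein, "position": r.position, "q_value": r.q_value}
        for r in records
    ]
    pd.DataFrame(rows, columns=MONO_COLUMNS).to_csv(path, sep="\t", index=False)


def write_bead_model(assembly: Assembly, path, coords: np.ndarray | None = None) -> None:
    """Write a positioned assembly as a PDB pseudo-atom file.

    One HETATM per bead; one chain ID per component copy; residue number is
    the first residue the bead covers; occupancy is the covered fraction of
    a full bead (n_res / granularity); the B-factor column holds the bead
    radius in Å.
    """
    if coords is None:
        coords = assembly.coords
    coords = np.asarray(coords, dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ValueError("bead model has non-finite coordinates")
    if len(assembly.chains) > len(_CHAIN_IDS):
        raise ValueError(
            f"{len(assembly.chains)} chains exceed the {len(_CHAIN_IDS)} "
            "available PDB chain identifiers"
        )
    gran = assembly.topology.granularity
    lines = []
    serial = 0
    for i, bead in enumerate(assembly.beads):
        serial += 1
        chain_id = _CHAIN_IDS[assembly.chain_of[i]]
        x, y, z = coords[i]
        occ = bead.n_res / gran
        lines.append(
            f"HETATM{serial:5d}  BD  BEA {chain_id}{bead.first_res:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{bead.radius:6.2f}"
            f"           C  "
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_bead_model(path) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Read back a bead-model PDB: (centres, radii, chain id per bead)."""
    st = gemmi.read_structure(str(path))
    centres, radii, chains = [], [], []
    for model in st:
        for chain in model:
            for res in chain:
                for atom in res:
                    centres.append([atom.pos.x, atom.pos.y, atom.pos.z])
                    radii.append(atom.b_iso)
                    chains.append(chain.name)
        break  # model 1 only
    return np.array(centres), np.array(radii), chains


def write_density_map(density_map, path, combined: np.ndarray | None = None) -> None:
    """Write a localization density as a CCP4/MRC volume.

    By default the per-bead probability histograms are summed into one
    volume (expected number of bead centres per voxel).  Pass ``combined``
    to write an arbitrary grid defined on the map's lattice instead.
    """
    grid_values = density_map.combined() if combined is None else combined
    if grid_values.size == 0 or not np.any(grid_values):
        raise ValueError("refusing to write an empty density map")
    nx, ny, nz = grid_values.shape
    grid = gemmi.FloatGrid(nx, ny, nz)
    grid.set_unit_cell(
        gemmi.UnitCell(
            nx * density_map.bin_size,
            ny * density_map.bin_size,
            nz * density_map.bin_size,
            90.0,
            90.0,
            90.0,
        )
    )
    arr = np.array(grid, copy=False)
    arr[...] = grid_values.astype(np.float32)
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = grid
    ccp4.update_ccp4_header()
    # encode the real-space origin of voxel (0,0,0)
    ccp4.set_header_float(50, float(density_map.origin[0]))
    ccp4.set_header_float(51, float(density_map.origin[1]))
    ccp4.set_header_float(52, float(density_map.origin[2]))
    ccp4.write_ccp4_map(str(path))


def read_density_map(path) -> tuple[np.ndarray, float, np.ndarray]:
    """Read a CCP4/MRC volume: (values, voxel size Å, origin Å)."""
    ccp4 = gemmi.read_ccp4_map(str(path))
    grid = ccp4.grid
    values = np.array(grid, copy=True)
    voxel = grid.unit_cell.a / grid.nu
    origin = np.array(
        [ccp4.header_float(50), ccp4.header_float(51), ccp4.header_float(52)]
    )
    return values, float(voxel), origin


# ---------------------------------------------------------------------------
# configuration


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def dump_config(cfg: dict, path) -> None:
    def _clean(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return _clean(dataclasses.asdict(obj))
        if isinstance(obj, dict):
            return {k: _clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_clean(v) for v in obj]
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        return obj

    with open(path, "w") as fh:
        yaml.safe_dump(_clean(cfg), fh, sort_keys=False)


def topology_from_config(cfg: dict, sequences: dict[str, str]) -> AssemblyTopology:
    """Build an AssemblyTopology from the ``topology`` block of a config."""
    top = cfg.get("topology", {})
    symmetry = None
    if "symmetry" in top and top["symmetry"] is not None:
        symmetry = RigidTransform(
            np.array(top["symmetry"]["rotation"], dtype=float),
            np.array(top["symmetry"]["translation"], dtype=float),
        )
    boxes = {
        name: Box(np.array(b["lo"], dtype=float), np.array(b["hi"], dtype=float))
        for name, b in top.get("bounding_boxes", {}).items()
    }
    return AssemblyTopology(
        sequences=sequences,
        copy_count=int(top.get("copy_count", 2)),
        granularity=int(top.get("granularity", 10)),
        symmetry=symmetry,
        subcomplex_groups=[list(g) for g in top.get("subcomplex_groups", [])],
        bounding_boxes=boxes,
    )


def write_json_report(report: dict, path) -> None:
    def _default(obj):
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        raise TypeError(f"not JSON serializable: {type(obj)}")

    Path(path).write_text(json.dumps(report, indent=2, default=_default) + "\n")
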