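"""Validation of cross-link datasets against reference atomic structures.

Given a PDB structure of a complex and its cross-link/mono-link tables,
compute the Cα–Cα distance of every mappable unique distance restraint, the
fraction within the span of the cross-linker (~30 Å for DSS), the
enrichment of short distances relative to the background of all lysine
pairs, and the fraction of lysines ever seen modified by the reagent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np

from .io import CrossLinkRecord, MonoLinkRecord

__all__ = [
    "ReferenceStructure",
    "map_distances",
    "fraction_within",
    "enrichment_profile",
    "monolink_coverage",
]


@dataclass
class ReferenceStructure:
    """Cα coordinates of a reference structure plus a register mapping.

    ``register`` maps a dataset protein name to the list of equivalent
    structure chains (with a residue-number offset each): for
    homo-oligomers every equivalent chain is listed and distances take the
    minimum over chain assignments, mirroring the ambiguity rule used in
    modelling.  Model 1 is used for multi-model files.
    """

    ca: dict[tuple[str, int], np.ndarray]
    lysines: list[tuple[str, int]]
    register: dict[str, list[tuple[str, int]]] = field(default_factory=dict)

    @classmethod
    def from_pdb(
        cls, path, register: dict[str, list[tuple[str, int]]] | None = None
    ) -> "ReferenceStructure":
        st = gemmi.read_structure(str(path))
        st.setup_entities()
        ca: dict[tuple[str, int], np.ndarray] = {}
        lysines: list[tuple[str, int]] = []
        model = st[0]  # model 1
        chains_seen = []
        for chain in model:
            chains_seen.append(chain.name)
            for res in chain:
                atom = res.find_atom("CA", "*")
                if atom is None:
                    continue
                key = (chain.name, res.seqid.num)
                if key in ca:
                    raise ValueError(f"duplicate Cα for {key} in {path}")
                ca[key] = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                if res.name == "LYS":
                    lysines.append(key)
        if register is None:
            register = {name: [(name, 0)] for name in chains_seen}
        return cls(ca=ca, lysines=lysines, register=register)

    def ca_coord(self, chain: str, residue: int) -> np.ndarray | None:
        return self.ca.get((chain, residue))


def map_distances(
    udrs: list[CrossLinkRecord], structure: ReferenceStructure
) -> dict[tuple, float | None]:
    """Cα–Cα distance per UDR; unmappable restraints flagged with None.

    For proteins mapped to several equivalent chains, the minimum distance
    over chain assignments is reported.
    """
    out: dict[tuple, float | None] = {}
    any_mapped = False
    for rec in udrs:
        best: float | None = None
        for chain_a, off_a in structure.register.get(rec.protein_a, []):
            pa = structure.ca_coord(chain_a, rec.position_a + off_a)
            if pa is None:
                continue
            for chain_b, off_b in structure.register.get(rec.protein_b, []):
                pb = structure.ca_coord(chain_b, rec.position_b + off_b)
                if pb is None:
                    continue
                d = float(np.linalg.norm(pa - pb))
                if best is None or d < best:
                    best = d
        out[rec.udr_key] = best
        if best is not None:
            any_mapped = True
    if udrs and not any_mapped:
        raise ValueError("structure contains neither endpoint of any UDR")
    return out


def fraction_within(distances, span: float) -> float:
    """Fraction of mapped Cα–Cα distances <= ``span`` Å."""
    vals = [d for d in _dist_values(distances) if d is not None]
    if not vals:
        raise ValueError("no mapped distances")
    return sum(d <= span for d in vals) / len(vals)


def _dist_values(distances):
    if isinstance(distances, dict):
        return list(distances.values())
    return list(distances)


def enrichment_profile(
    distances,
    structure: ReferenceStructure,
    bin_width: float = 5.0,
    enrichment_at: float = 20.0,
) -> dict:
    """Observed vs all-lysine-pair distance histograms and <cutoff enrichment.

    The background is the distribution of Cα–Cα distances over *all* lysine
    pairs of the structure.  Both histograms are normalized to sum to 1;
    the enrichment ratio is the observed cumulative fraction at
    ``enrichment_at`` Å divided by the background cumulative fraction.
    """
    observed = np.array([d for d in _dist_values(distances) if d is not None])
    if observed.size == 0:
        raise ValueError("no mapped observed distances")
    lys = structure.lysines
    if len(lys) < 2:
        raise ValueError("structure has fewer than two lysines")
    pts = np.array([structure.ca[k] for k in lys])
    diff = pts[:, None, :] - pts[None, :, :]
    dmat = np.linalg.norm(diff, axis=-1)
    iu, ju = np.triu_indices(len(lys), 1)
    background = dmat[iu, ju]
    top = max(observed.max(), background.max()) + bin_width
    edges = np.arange(0.0, top + bin_width, bin_width)
    obs_hist, _ = np.histogram(observed, bins=edges)
    bg_hist, _ = np.histogram(background, bins=edges)
    obs_hist = obs_hist / obs_hist.sum()
    bg_hist = bg_hist / bg_hist.sum()
    obs_cum = float(np.mean(observed <= enrichment_at))
    bg_cum = float(np.mean(background <= enrichment_at))
    ratio = float("inf") if bg_cum == 0 else obs_cum / bg_cum
    return {
        "bin_edges": edges,
        "observed": obs_hist,
        "background": bg_hist,
        "cutoff": enrichment_at,
        "observed_cumulative": obs_cum,
        "background_cumulative": bg_cum,
        "enrichment_ratio": ratio,
    }


def monolink_coverage(
    monolinks: list[MonoLinkRecord],
    sequences: dict[str, str],
    crosslinks: list[CrossLinkRecord] | None = None,
) -> float:
    """Fraction of lysines seen modified in mono-link or cross-link records."""
    total = 0
    lys_positions: dict[str, set[int]] = {}
    for name, seq in sequences.items():
        pos = {i + 1 for i, aa in enumerate(seq) if aa == "K"}
        lys_positions[name] = pos
        total += len(pos)
    if total == 0:
        raise ValueError("sequences contain no lysines")
    seen: set[tuple[str, int]] = set()
    for m in monolinks:
        if m.position in lys_positions.get(m.protein, ()):
            seen.add((m.protein, m.position))
    for x in crosslinks or []:
        for prot, pos in ((x.protein_a, x.position_a), (x.protein_b, x.position_b)):
            if pos in lys_positions.get(prot, ()):
                seen.add((prot, pos))
    return len(seen) / total
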