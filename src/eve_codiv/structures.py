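"""Structure model comparison: superposition, domain screening, RMSD bands.

Structure models (predicted NS1 folds) are compared by least-squares
rigid superposition of Cα atoms using the Kabsch algorithm (proper
rotations only — reflections are sign-corrected away). Residue pairing
between two models comes from a global alignment of their sequences.
Functional domains are delineated by a spatial screen: every residue
with an atom within a distance cutoff (default 5 Å) of a seed residue
set belongs to the domain. Similarity classes follow fixed RMSD bands:
<=2.0 Å highly similar, 2.0-3.0 Å moderately similar, >3.0 Å
significantly divergent.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["StructureModel", "SuperpositionResult", "load_structure",
           "qc_filter", "residue_correspondence", "kabsch_rmsd",
           "screen_domain", "classify_rmsd", "walker_a_seeds",
           "superpose_pair"]

WALKER_A = re.compile(r"G.{4}GK[TS]")


@dataclass
class StructureModel:
    model_id: str
    residue_ids: np.ndarray          # strictly increasing residue numbers
    sequence: str                    # one-letter, parallel to residue_ids
    ca: np.ndarray                   # (n, 3) Cα coordinates, Å
    atoms: dict | None = None        # residue id -> (k, 3) all-atom coords
    ptm: float | None = None
    iptm: float | None = None

    def __post_init__(self):
        self.residue_ids = np.asarray(self.residue_ids)
        self.ca = np.asarray(self.ca, dtype=float)
        if len(self.sequence) != len(self.residue_ids) or \
                self.ca.shape != (len(self.sequence), 3):
            raise ValueError("sequence, residue ids and Cα must be parallel")
        if np.any(np.diff(self.residue_ids) <= 0):
            raise ValueError("residue ids must be strictly increasing")
        if not np.all(np.isfinite(self.ca)):
            raise ValueError("non-finite coordinates")


@dataclass
class SuperpositionResult:
    pair: tuple[str, str]
    n_pairs: int
    global_rmsd: float
    rotation: np.ndarray
    translation: np.ndarray
    domain_rmsds: dict = field(default_factory=dict)
    classes: dict = field(default_factory=dict)


def load_structure(path: str | Path, model_id: str | None = None
                   ) -> StructureModel:
    """Read a PDB or mmCIF file (first model, first protein chain).

    A JSON sidecar ``<stem>.json`` with pTM/ipTM confidence metadata is
    picked up automatically when present.
    """
    import biotite.structure as struc
    from biotite.sequence import ProteinSequence

    path = Path(path)
    if path.suffix.lower() in (".cif", ".mmcif"):
        import biotite.structure.io.pdbx as pdbx
        f = pdbx.CIFFile.read(str(path))
        arr = pdbx.get_structure(f, model=1)
    else:
        import biotite.structure.io.pdb as pdb
        f = pdb.PDBFile.read(str(path))
        arr = f.get_structure(model=1)
    arr = arr[struc.filter_amino_acids(arr)]
    if arr.array_length() == 0:
        raise ValueError(f"no protein atoms in {path}")
    chain = arr.chain_id[0]
    arr = arr[arr.chain_id == chain]
    ca = arr[arr.atom_name == "CA"]
    res_ids, seq, coords, atoms = [], [], [], {}
    for rid in np.unique(ca.res_id):
        sub = ca[ca.res_id == rid]
        res_ids.append(int(rid))
        try:
            seq.append(ProteinSequence.convert_letter_3to1(sub.res_name[0]))
        except Exception:
            seq.append("X")
        coords.append(sub.coord[0])
        all_sub = arr[arr.res_id == rid]
        atoms[int(rid)] = np.asarray(all_sub.coord, dtype=float)
    ptm = iptm = None
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        ptm = meta.get("ptm", meta.get("pTM"))
        iptm = meta.get("iptm", meta.get("ipTM"))
    return StructureModel(model_id=model_id or path.stem,
                          residue_ids=np.array(res_ids),
                          sequence="".join(seq),
                          ca=np.array(coords, dtype=float),
                          atoms=atoms, ptm=ptm, iptm=iptm)


def qc_filter(models: list[StructureModel], ptm_min: float = 0.5,
              iptm_min: float = 0.8) -> list[StructureModel]:
    """Keep models with pTM strictly above ``ptm_min`` and ipTM strictly
    above ``iptm_min``; models lacking a metric are retained with a
    warning."""
    kept = []
    for m in models:
        if m.ptm is None and m.iptm is None:
            warnings.warn(f"{m.model_id}: no confidence metadata; retained")
            kept.append(m)
            continue
        if m.ptm is not None and not m.ptm > ptm_min:
            continue
        if m.iptm is not None and not m.iptm > iptm_min:
            continue
        if m.ptm is None or m.iptm is None:
            warnings.warn(f"{m.model_id}: partial confidence metadata")
        kept.append(m)
    return kept


def residue_correspondence(a: StructureModel, b: StructureModel
                           ) -> list[tuple[int, int]]:
    """Index pairs (into a's and b's residue arrays) from a global
    sequence alignment of the two models."""
    if not a.sequence or not b.sequence:
        raise ValueError("empty model")
    from eve_codiv.distances import global_align
    ga, gb = global_align(a.sequence, b.sequence)
    pairs = []
    ia = ib = 0
    for x, y in zip(ga, gb):
        if x != "-" and y != "-":
            pairs.append((ia, ib))
        if x != "-":
            ia += 1
        if y != "-":
            ib += 1
    if not pairs:
        raise ValueError("no alignable residue pairs")
    return pairs


def kabsch_rmsd(coords_a: np.ndarray, coords_b: np.ndarray
                ) -> tuple[float, np.ndarray, np.ndarray]:
    """Least-squares rigid superposition of paired point sets.

    Returns (rmsd, rotation R, translation t) with det(R) = +1 such
    that ``coords_a @ R.T + t`` best matches ``coords_b``.
    """
    A = np.asarray(coords_a, dtype=float)
    B = np.asarray(coords_b, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError("paired (n, 3) coordinate sets required")
    if A.shape[0] < 2:
        raise ValueError("need at least 2 paired points")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    A0, B0 = A - ca, B - cb
    H = A0.T @ B0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    if d == 0:
        d = 1.0
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    diff = A0 @ R.T - B0
    rmsd = float(np.sqrt((diff ** 2).sum() / A.shape[0]))
    t = cb - ca @ R.T
    return rmsd, R, t


def screen_domain(model: StructureModel, seed_residues, cutoff: float = 5.0
                  ) -> list[int]:
    """Residue ids within ``cutoff`` Å of any seed residue's atoms,
    unioned with the seeds; contiguous runs shorter than 3 residues are
    pruned unless they contain a seed."""
    seeds = sorted(set(int(r) for r in seed_residues))
    if not seeds:
        raise ValueError("empty seed residue set")
    ids = set(model.residue_ids.tolist())
    missing = [s for s in seeds if s not in ids]
    if missing:
        raise ValueError(f"seed residues absent from model: {missing}")

    def coords_of(rid: int) -> np.ndarray:
        if model.atoms and rid in model.atoms:
            return model.atoms[rid]
        i = int(np.searchsorted(model.residue_ids, rid))
        return model.ca[i:i + 1]

    seed_xyz = np.vstack([coords_of(s) for s in seeds])
    selected = set(seeds)
    if cutoff > 0:
        for rid in model.residue_ids.tolist():
            if rid in selected:
                continue
            xyz = coords_of(int(rid))
            d2 = ((xyz[:, None, :] - seed_xyz[None, :, :]) ** 2).sum(-1)
            if d2.min() <= cutoff ** 2:
                selected.add(int(rid))
    # prune short runs (by residue numbering) not containing a seed
    sel = sorted(selected)
    runs, cur = [], [sel[0]]
    for r in sel[1:]:
        if r == cur[-1] + 1:
            cur.append(r)
        else:
            runs.append(cur)
            cur = [r]
    runs.append(cur)
    out = []
    seed_set = set(seeds)
    for run in runs:
        if len(run) >= 3 or seed_set & set(run):
            out.extend(run)
    return out


def classify_rmsd(rmsd: float) -> str:
    """Similarity band of an RMSD value (Å)."""
    if rmsd < 0:
        raise ValueError("RMSD cannot be negative")
    if rmsd <= 2.0:
        return "highly_similar"
    if rmsd <= 3.0:
        return "moderately_similar"
    return "significantly_divergent"


def walker_a_seeds(model: StructureModel) -> list[int]:
    """Residue ids of Walker-A motif matches (G-x(4)-G-K-[TS]) — the
    default anchor for the ATPase-domain screen."""
    out = []
    for m in WALKER_A.finditer(model.sequence):
        out.extend(int(model.residue_ids[i])
                   for i in range(m.start(), m.end()))
    return out


def superpose_pair(a: StructureModel, b: StructureModel,
                   domains: dict[str, tuple[list[int], list[int]]] | None
                   = None, reject_outliers: bool = False,
                   max_cycles: int = 5) -> SuperpositionResult:
    """Global superposition of two models plus optional per-domain RMSDs.

    ``domains`` maps a label to (residue ids in a, residue ids in b);
    domain RMSDs are computed from independent superpositions of the
    corresponded residues restricted to the domain, and classified into
    the fixed similarity bands. ``reject_outliers`` enables align-style
    refinement cycles dropping pairs deviating more than twice the
    current RMSD.
    """
    pairs = residue_correspondence(a, b)
    ia = np.array([p[0] for p in pairs])
    ib = np.array([p[1] for p in pairs])
    A, B = a.ca[ia], b.ca[ib]
    rmsd, R, t = kabsch_rmsd(A, B)
    if reject_outliers:
        keep = np.ones(len(A), dtype=bool)
        for _ in range(max_cycles):
            dev = np.linalg.norm(A @ R.T + t - B, axis=1)
            new_keep = dev <= max(2.0 * rmsd, 1e-6)
            if new_keep.sum() < 3 or np.array_equal(new_keep, keep):
                break
            keep = new_keep
            rmsd, R, t = kabsch_rmsd(A[keep], B[keep])
        A, B = A[keep], B[keep]
    res = SuperpositionResult(pair=(a.model_id, b.model_id),
                              n_pairs=len(A), global_rmsd=rmsd,
                              rotation=R, translation=t)
    for label, (res_a, res_b) in (domains or {}).items():
        sa, sb = set(res_a), set(res_b)
        mask = [(a.residue_ids[p[0]] in sa) and (b.residue_ids[p[1]] in sb)
                for p in pairs]
        mask = np.array(mask)
        if mask.sum() >= 2:
            d_rmsd, _, _ = kabsch_rmsd(a.ca[ia[mask]], b.ca[ib[mask]])
            res.domain_rmsds[label] = d_rmsd
            res.classes[label] = classify_rmsd(d_rmsd)
    return res
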