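"""File formats: PDB structures, FASTA libraries, CSV tables, configs.

PDB reading/writing is delegated to biotite; models are written with a
single chain "A", contiguous 1-based residue numbering, occupancy 1.00
and B-factor 0.00.  Coordinates are Å throughout; intervals in CSV
manifests are closed and 1-based.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.SeqUtils import seq1, seq3
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .backbone import BACKBONE_ATOMS, BackboneModel, Residue
from .errors import InvalidInputError, SchemaError
from .sortseq import GateInfo, SortSeqCounts

__all__ = [
    "read_pdb", "read_pdb_model", "write_pdb",
    "read_fasta", "write_fasta",
    "read_counts_csv", "read_curves_csv",
    "read_config", "write_run_log",
]

_ELEMENTS = {"N": "N", "CA": "C", "C": "C", "O": "O"}


def _prevalidate_pdb(path) -> None:
    """Catch structurally broken ATOM records with a line number before
    handing the file to the parser."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec in ("ATOM", "HETATM") and len(line.rstrip("\n")) < 54:
                raise SchemaError(
                    f"{path}: truncated {rec} record at line {lineno}")


def read_pdb(path) -> dict:
    """Parse backbone content of a PDB file.

    Returns ``{chain_id: {residue_number: {"aa": one_letter,
    "atoms": {name: xyz}}}}`` restricted to N/CA/C/O atoms.  HETATM
    records are skipped with a warning; residues missing backbone atoms
    are kept as gaps (their dict simply lacks the atom).
    """
    _prevalidate_pdb(path)
    pdb = PDBFile.read(str(path))
    atoms = pdb.get_structure(model=1)
    if atoms.hetero.any():
        warnings.warn(f"{path}: ignoring {int(atoms.hetero.sum())} HETATM atoms")
        atoms = atoms[~atoms.hetero]
    atoms = atoms[np.isin(atoms.atom_name, BACKBONE_ATOMS)]
    out: dict = {}
    for i in range(atoms.array_length()):
        chain = str(atoms.chain_id[i])
        resnum = int(atoms.res_id[i])
        res = out.setdefault(chain, {}).setdefault(
            resnum, {"aa": _one_letter(str(atoms.res_name[i])), "atoms": {}})
        res["atoms"][str(atoms.atom_name[i])] = atoms.coord[i].astype(float)
    return out


def _one_letter(res_name: str) -> str:
    try:
        letter = seq1(res_name.capitalize())
    except Exception:
        letter = "X"
    return letter if letter.isalpha() else "X"


def read_pdb_model(path, chain: str | None = None) -> BackboneModel:
    """Read one chain of a PDB file as a BackboneModel.

    Residues missing any of N/CA/C/O are dropped with a warning (a
    recorded gap, not a crash).
    """
    parsed = read_pdb(path)
    if chain is None:
        chain = sorted(parsed)[0]
    if chain not in parsed:
        raise InvalidInputError(f"chain {chain!r} not in {path}")
    residues = []
    for resnum in sorted(parsed[chain]):
        res = parsed[chain][resnum]
        if any(a not in res["atoms"] for a in BACKBONE_ATOMS):
            warnings.warn(f"{path}: residue {chain}/{resnum} misses backbone "
                          "atoms; skipped")
            continue
        coords = np.stack([res["atoms"][a] for a in BACKBONE_ATOMS])
        residues.append(Residue(len(residues) + 1, res["aa"], coords))
    if not residues:
        raise InvalidInputError(f"no complete backbone residues in {path}")
    return BackboneModel(residues, {"source": str(path)})


def write_pdb(model: BackboneModel, path) -> None:
    """Write a backbone model as standard fixed-column ATOM records."""
    n_atoms = 4 * len(model)
    arr = struc.AtomArray(n_atoms)
    arr.coord = model.coords.astype(np.float32)
    arr.chain_id = np.full(n_atoms, "A")
    arr.res_id = np.repeat([r.index for r in model.residues], 4)
    arr.res_name = np.repeat([_three_letter(r.aa) for r in model.residues], 4)
    arr.atom_name = np.tile(list(BACKBONE_ATOMS), len(model))
    arr.element = np.tile([_ELEMENTS[a] for a in BACKBONE_ATOMS], len(model))
    arr.hetero = np.zeros(n_atoms, bool)
    arr.set_annotation("occupancy", np.ones(n_atoms, np.float32))
    arr.set_annotation("b_factor", np.zeros(n_atoms, np.float32))
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))


def _three_letter(aa: str) -> str:
    try:
        return seq3(aa).upper()
    except Exception:
        return "UNK"


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> dict[str, str]:
    """Sequences keyed by record id; duplicate ids are rejected."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise SchemaError(f"duplicate sequence id {rec.id!r} in {path}")
        out[rec.id] = str(rec.seq)
    return out


def write_fasta(sequences: dict[str, str], path, width: int = 60) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sequences.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# CSV tables

#: gate id of the pre-sort pool rows in a counts CSV
REFERENCE_GATE = "reference"


def read_counts_csv(counts_path, gates_path) -> SortSeqCounts:
    """Load sort-seq counts (CSV) plus the gate manifest (JSON).

    Counts CSV columns: variant, gate_id, reads (and optionally
    sequence); rows with gate_id ``reference`` form the pre-sort pool.
    The manifest is a JSON list of objects with gate_id, round, target,
    concentration_nM and optional fraction_collected.
    """
    df = pd.read_csv(counts_path)
    required = {"variant", "gate_id", "reads"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{counts_path}: missing columns {sorted(missing)}")
    if (df["reads"] < 0).any():
        raise SchemaError(f"{counts_path}: negative read counts")
    with open(gates_path) as fh:
        manifest = json.load(fh)
    gates = {g["gate_id"]: GateInfo(g["gate_id"], int(g["round"]),
                                    str(g["target"]), float(g["concentration_nM"]),
                                    float(g.get("fraction_collected", 1.0)))
             for g in manifest}
    wide = df.pivot_table(index="variant", columns="gate_id", values="reads",
                          aggfunc="sum", fill_value=0.0)
    if REFERENCE_GATE not in wide.columns:
        raise SchemaError(f"{counts_path}: no '{REFERENCE_GATE}' gate rows")
    reference = wide[REFERENCE_GATE]
    counts = wide.drop(columns=[REFERENCE_GATE])
    sequences = {}
    if "sequence" in df.columns:
        sequences = (df.dropna(subset=["sequence"])
                     .drop_duplicates("variant").set_index("variant")["sequence"]
                     .to_dict())
    return SortSeqCounts(counts, reference, gates, sequences)


def write_counts_csv(data: SortSeqCounts, counts_path, gates_path) -> None:
    rows = []
    for variant in data.counts.index:
        rows.append((variant, REFERENCE_GATE, data.reference[variant]))
        for gate in data.counts.columns:
            rows.append((variant, gate, data.counts.loc[variant, gate]))
    pd.DataFrame(rows, columns=["variant", "gate_id", "reads"]).to_csv(
        counts_path, index=False)
    with open(gates_path, "w") as fh:
        json.dump([{"gate_id": g.gate_id, "round": g.round, "target": g.target,
                    "concentration_nM": g.concentration_nM,
                    "fraction_collected": g.fraction_collected}
                   for g in data.gates.values()], fh, indent=1)


def read_curves_csv(path, required_columns: tuple[str, ...]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(required_columns) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# config and run logs

KNOWN_CONFIG_KEYS = {
    "seed", "out_dir", "log_level", "tries", "top_k", "closure_threshold",
    "clash_min_distance", "pairing_max_no_distance", "pairing_min_contacts",
    "sheet_max_ca_distance", "sheet_min_dot", "rg_max", "cavity_volume_max",
    "sigma_scale", "max_carryover", "pseudocount", "fold_threshold",
    "kd_max_nM", "temperature", "depth",
}


def read_config(path) -> dict:
    """YAML or JSON config; unknown keys warn and are dropped."""
    text = Path(path).read_text()
    cfg = yaml.safe_load(text) or {}
    if not isinstance(cfg, dict):
        raise SchemaError(f"{path}: config must be a mapping")
    unknown = set(cfg) - KNOWN_CONFIG_KEYS
    for key in sorted(unknown):
        warnings.warn(f"{path}: unknown config key {key!r} ignored")
        cfg.pop(key)
    return cfg


def write_run_log(path, command: str, seed: int, parameters: dict,
                  input_paths: list | None = None) -> None:
    """Machine-readable record of one CLI invocation."""
    checksums = {}
    for p in input_paths or []:
        p = Path(p)
        if p.is_file():
            checksums[str(p)] = hashlib.sha256(p.read_bytes()).hexdigest()
    with open(path, "w") as fh:
        json.dump({"command": command, "seed": seed,
                   "parameters": {k: repr(v) for k, v in parameters.items()},
                   "input_checksums": checksums}, fh, indent=1, sort_keys=True)
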