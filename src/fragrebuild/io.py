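"""Plain-text serialization: SMILES record files, libraries, traces, config.

SMILES record files hold one record per line —
``<id><TAB><smiles>[<TAB><binding_energy>]`` — with ``#`` comment lines
ignored.  A fragment library round-trips through a directory of
``sl_star.smi`` (headers, markers as ``*``, parent id in the third column),
``sl.smi`` (bodies) and an ``accounting.txt`` key=value sidecar.
"""

from __future__ import annotations

from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import yaml

from . import chem
from .annealing import SAConfig
from .errors import ContractError
from .fragments import FragmentBody, FragmentHeader, FragmentLibrary
from .rebuild import NewLigand, ReconstructionAccounting


def read_smiles_records(path) -> List[Tuple[str, str, Optional[float]]]:
    """Parse a SMILES record file into (id, smiles, binding_energy) tuples."""
    out = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ContractError(f"{path}:{lineno}: expected '<id>\\t<smiles>[\\t<be>]'")
        be = float(parts[2]) if len(parts) > 2 and parts[2] != "" else None
        out.append((parts[0], parts[1], be))
    return out


def write_smiles_records(path, records: Sequence[Tuple[str, str, Optional[float]]]) -> None:
    lines = []
    for rid, smiles, be in records:
        lines.append(f"{rid}\t{smiles}" + (f"\t{be}" if be is not None else ""))
    Path(path).write_text("\n".join(lines) + "\n")


def save_library(lib: FragmentLibrary, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    with open(d / "sl_star.smi", "w") as fh:
        fh.write("# headers: id, SMILES with attachment markers, parent ligand id\n")
        for i, h in enumerate(lib.headers):
            fh.write(f"H{i:04d}\t{h.smiles_with_markers}\t{h.parent_id}\n")
    with open(d / "sl.smi", "w") as fh:
        fh.write("# bodies: id, SMILES, parent ligand id\n")
        for i, b in enumerate(lib.bodies):
            fh.write(f"B{i:04d}\t{b.molecule.smiles_canonical}\t{b.parent_id}\n")
    (d / "accounting.txt").write_text(
        f"nkl={lib.n_kl}\nnfl={lib.n_fl}\ndf={lib.n_df}\nnsl={lib.n_sl}\n"
    )


def _read_fragment_file(path) -> List[Tuple[str, str]]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        _fid, smiles, parent = line.split("\t")
        out.append((smiles, parent))
    return out


def load_library(directory) -> FragmentLibrary:
    d = Path(directory)
    sidecar = dict(
        line.split("=", 1)
        for line in (d / "accounting.txt").read_text().splitlines()
        if line.strip()
    )
    headers = [
        FragmentHeader(
            smiles_with_markers=s,
            n_attach=sum(1 for a in chem.rdmol(s).GetAtoms() if a.GetAtomicNum() == 0),
            parent_id=p,
        )
        for s, p in _read_fragment_file(d / "sl_star.smi")
    ]
    bodies = [
        FragmentBody(molecule=chem.canonicalize(s), parent_id=p)
        for s, p in _read_fragment_file(d / "sl.smi")
    ]
    return FragmentLibrary(
        headers=headers,
        bodies=bodies,
        n_fl=int(sidecar["nfl"]),
        n_df=int(sidecar["df"]),
        n_sl=int(sidecar["nsl"]),
        n_kl=int(sidecar.get("nkl", 0)),
    )


def write_new_ligands(path, ligands: Sequence[NewLigand]) -> None:
    with open(path, "w") as fh:
        fh.write("# id, SMILES, header parent, body parents\n")
        for i, nl in enumerate(ligands):
            fh.write(
                f"NL{i:05d}\t{nl.molecule.smiles_canonical}"
                f"\t{nl.header_parent}\t{'+'.join(nl.body_parents)}\n"
            )


def write_accounting(path, acc: ReconstructionAccounting) -> None:
    Path(path).write_text(
        "\n".join(
            f"{k}={getattr(acc, k)}"
            for k in ("n_kl", "n_fl", "df", "n_sl", "generated", "rnl", "rnl_coupling", "dnl", "n")
        )
        + "\n"
    )


def load_config(path) -> dict:
    """YAML config: 'sa' section -> SAConfig kwargs, plus scorer options."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    cfg = dict(raw)
    cfg["sa"] = SAConfig(**raw.get("sa", {}))
    return cfg
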