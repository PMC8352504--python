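"""File formats: FASTA sequences, structure lists, potential tables, grids.

Structure lists are plain text, one ``dot-bracket<TAB>energy`` line per
structure (energy in kcal/mol, two decimals); readers tolerate extra
columns so output of other sampling tools can be scored directly.
"""

from __future__ import annotations

import json
import hashlib
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .energy import PairPotential
from .landscape import BarrierTree
from .projection import DistanceClassGrid
from .structures import RnaSequence, SecondaryStructure, parse_dotbracket

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_structure_list",
    "write_structure_list",
    "read_potential_tsv",
    "write_potential_tsv",
    "write_grid_tsv",
    "read_grid_tsv",
    "write_barrier_tree",
    "config_sidecar",
]


def read_fasta(path: str | Path) -> list[RnaSequence]:
    return [
        RnaSequence(str(rec.seq), id=rec.id)
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(path: str | Path, seqs: Iterable[RnaSequence]) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n{s.residues}\n")


def write_structure_list(
    path: str | Path,
    items: Iterable[tuple[SecondaryStructure, float]],
    header: str | None = None,
) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for s, e in items:
            fh.write(f"{s.dotbracket}\t{e:.2f}\n")


def read_structure_list(
    path: str | Path, seq: RnaSequence | None = None
) -> list[tuple[SecondaryStructure, float | None]]:
    out: list[tuple[SecondaryStructure, float | None]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", ">")):
                continue
            fields = line.split()
            s = parse_dotbracket(fields[0], seq)
            e = None
            if len(fields) > 1:
                try:
                    e = float(fields[1])
                except ValueError:
                    pass
            out.append((s, e))
    return out


def write_potential_tsv(path: str | Path, potential: PairPotential) -> None:
    rows = [
        {"i": i, "j": j, "E_ij": float(v)}
        for (i, j), v in sorted(potential.entries.items())
    ]
    pd.DataFrame(rows, columns=["i", "j", "E_ij"]).to_csv(path, sep="\t", index=False)


def read_potential_tsv(path: str | Path) -> PairPotential:
    df = pd.read_csv(path, sep="\t")
    return PairPotential.from_entries(
        (int(r.i), int(r.j), float(r.E_ij)) for r in df.itertuples()
    )


def write_grid_tsv(path: str | Path, grid: DistanceClassGrid) -> None:
    rows = []
    for (d1, d2), cell in sorted(grid.cells.items()):
        rows.append(
            {
                "d1": d1,
                "d2": d2,
                "best_energy": round(cell.best_energy, 6),
                "G": round(grid.free_energy(d1, d2), 6),
                "count": cell.count,
                "best_structure": cell.best_structure.dotbracket,
            }
        )
    pd.DataFrame(
        rows, columns=["d1", "d2", "best_energy", "G", "count", "best_structure"]
    ).to_csv(path, sep="\t", index=False)


def read_grid_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_barrier_tree(path_txt: str | Path, path_json: str | Path, tree: BarrierTree) -> None:
    """Barriers-style table (index, dot-bracket, energy, father, barrier) + JSON."""
    ids = {s: k + 1 for k, (s, _) in enumerate(tree.leaves)}
    father: dict[int, int] = {}
    barrier: dict[int, float] = {}
    for mg in tree.merges:
        child = ids[mg.shallower_min]
        if child not in father:
            father[child] = ids[mg.deeper_min]
            e_child = dict(tree.leaves)[mg.shallower_min]
            barrier[child] = mg.saddle_energy - e_child
    with open(path_txt, "w") as fh:
        for (s, e) in tree.leaves:
            k = ids[s]
            fh.write(
                f"{k:4d} {s.dotbracket} {e:8.2f} {father.get(k, 0):4d} "
                f"{barrier.get(k, 0.0):8.2f}\n"
            )
    payload = {
        "merge_threshold": tree.merge_threshold,
        "complete": tree.complete,
        "leaves": [
            {"index": ids[s], "structure": s.dotbracket, "energy": e}
            for s, e in tree.leaves
        ],
        "merges": [
            {
                "deeper": mg.deeper_min.dotbracket,
                "shallower": mg.shallower_min.dotbracket,
                "saddle": mg.saddle.dotbracket,
                "saddle_energy": mg.saddle_energy,
            }
            for mg in tree.merges
        ],
    }
    Path(path_json).write_text(json.dumps(payload, indent=1))


def config_sidecar(path: str | Path, config: dict) -> None:
    """Write a JSON sidecar embedding the config and its hash for reproducibility."""
    blob = json.dumps(config, sort_keys=True, default=str)
    payload = dict(config)
    payload["config_sha256"] = hashlib.sha256(blob.encode()).hexdigest()
    Path(path).write_text(json.dumps(payload, indent=1, default=str))
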