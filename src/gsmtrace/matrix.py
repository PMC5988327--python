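"""Stoichiometric matrix export (TSV, compounds x reactions).

Entries are signed stoichiometric coefficients (reactants negative,
products positive; a compound on both sides nets out). Rows and columns are
ordered lexicographically so the export is deterministic.
"""

from __future__ import annotations

import os
from typing import Union

from .model import GsmtraceError, Model


def stoichiometric_matrix(model: Model) -> tuple[list[str], list[str], list[list[float]]]:
    """Return (compound ids, reaction ids, dense row-major matrix)."""
    reactions = sorted(e.id for e in model.reactions())
    if not reactions:
        raise GsmtraceError("stoichiometric matrix needs at least one reaction")
    compounds = sorted(
        e.id for e in model.entities.values() if e.etype in ("compound", "class")
    )
    row_index = {cid: i for i, cid in enumerate(compounds)}
    matrix = [[0.0] * len(reactions) for _ in compounds]
    for j, rid in enumerate(reactions):
        for relation in model.relations_from(rid, "consumes"):
            matrix[row_index[relation.object]][j] -= relation.coefficient
        for relation in model.relations_from(rid, "produces"):
            matrix[row_index[relation.object]][j] += relation.coefficient
    return compounds, reactions, matrix


def export_matrix(model: Model, path: Union[str, os.PathLike]) -> None:
    """Write the stoichiometric matrix as TSV with id header row/column."""
    compounds, reactions, matrix = stoichiometric_matrix(model)
    with open(path, "w", encoding="utf-8", newline="\n") as handle:
        handle.write("compound\t" + "\t".join(reactions) + "\n")
        for cid, row in zip(compounds, matrix):
            handle.write(cid + "\t" + "\t".join("%g" % v for v in row) + "\n")
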