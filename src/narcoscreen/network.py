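"""Two-mode hospital-patient network and its one-mode projection.

The two-mode (bipartite) network has one node per hospital and per
patient appearing in the analysis subset, and one undirected edge per
distinct (patient, hospital) pair, weighted by the number of
prescriptions the pair shares.  The one-mode hospital network is
obtained by incidence-matrix multiplication: with ``B`` the binary
patient-by-hospital incidence matrix, hospitals ``i`` and ``j`` are
joined with weight ``(B^T B)_{ij}`` — the number of distinct patients
they share — and the diagonal is discarded.  A prescription-weighted
variant (``N^T N`` with ``N`` the count matrix) is available for
sensitivity analysis.
"""

from __future__ import annotations

from collections import Counter
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import scipy.sparse as sp

from .records import PrescriptionRecord, ValidationError

HOSPITAL = "Hospital"
PATIENT = "Patient"


def build_two_mode(records: Sequence[PrescriptionRecord]) -> nx.Graph:
    """Build the undirected bipartite hospital-patient network.

    Node attribute ``category`` is ``"Hospital"`` or ``"Patient"``
    (plus the conventional ``bipartite`` 0/1 marker); edge attribute
    ``weight`` is the prescription count of the pair.  Empty input gives
    an empty graph.

    Raises
    ------
    ValidationError
        If some token is used both as a patient id and a hospital id
        (the two namespaces must be disjoint).
    """
    patients = {r.patient_id for r in records}
    hospitals = {r.hospital_id for r in records}
    clash = patients & hospitals
    if clash:
        raise ValidationError(
            f"ids used as both patient and hospital: {sorted(clash)[:5]}"
        )
    weights = Counter((r.patient_id, r.hospital_id) for r in records)
    G = nx.Graph()
    G.add_nodes_from(sorted(patients), category=PATIENT, bipartite=0)
    G.add_nodes_from(sorted(hospitals), category=HOSPITAL, bipartite=1)
    for (pid, hid), w in sorted(weights.items()):
        G.add_edge(pid, hid, weight=int(w))
    return G


def hospital_nodes(G: nx.Graph) -> list[str]:
    """Hospital nodes of a two-mode (or projected) network, sorted."""
    return sorted(n for n, d in G.nodes(data=True)
                  if d.get("category") == HOSPITAL)


def patient_nodes(G: nx.Graph) -> list[str]:
    return sorted(n for n, d in G.nodes(data=True)
                  if d.get("category") == PATIENT)


def incidence_matrix(
    G: nx.Graph, weighted: bool = False
) -> tuple[sp.csr_array, list[str], list[str]]:
    """Patient-by-hospital incidence matrix of a two-mode network.

    Returns ``(matrix, patients, hospitals)`` with rows/columns in the
    sorted node orders; entries are prescription counts when
    ``weighted`` else 0/1.
    """
    patients = patient_nodes(G)
    hospitals = hospital_nodes(G)
    p_index = {p: i for i, p in enumerate(patients)}
    h_index = {h: i for i, h in enumerate(hospitals)}
    rows, cols, vals = [], [], []
    for u, v, data in G.edges(data=True):
        pid, hid = (u, v) if u in p_index else (v, u)
        rows.append(p_index[pid])
        cols.append(h_index[hid])
        vals.append(float(data.get("weight", 1)) if weighted else 1.0)
    B = sp.csr_array(
        (vals, (rows, cols)), shape=(len(patients), len(hospitals))
    )
    return B, patients, hospitals


def project_one_mode(two_mode: nx.Graph, weighted: bool = False) -> nx.Graph:
    """Project the two-mode network onto hospitals by matrix multiplication.

    Edge weight is the off-diagonal of ``B^T B``: the number of distinct
    shared patients (``weighted=True`` uses the count matrix ``N`` and
    yields ``N^T N``, summing products of prescription counts over
    shared patients).  Hospitals sharing no patient remain as isolated
    nodes, keeping per-hospital reports complete.
    """
    B, _, hospitals = incidence_matrix(two_mode, weighted=weighted)
    M = (B.T @ B).tocoo()
    H = nx.Graph()
    for h in hospitals:
        H.add_node(h, category=HOSPITAL,
                   **{k: v for k, v in two_mode.nodes[h].items()
                      if k not in ("category", "bipartite")})
    order = np.lexsort((M.col, M.row))
    for i, j, w in zip(M.row[order], M.col[order], M.data[order]):
        if i < j and w > 0:
            H.add_edge(hospitals[i], hospitals[j],
                       weight=int(w) if float(w).is_integer() else float(w))
    return H


# --------------------------------------------------------------------------
# Exports
# --------------------------------------------------------------------------

def write_graphml(G: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(G, str(path))


def read_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(str(path))


def write_gexf(G: nx.Graph, path: str | Path) -> None:
    nx.write_gexf(G, str(path))


def write_edge_list(
    G: nx.Graph, path: str | Path, header_comment: str | None = None
) -> None:
    """Plain weighted edge list: ``source,target,weight,type``."""
    import csv

    with open(Path(path), "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["source", "target", "weight", "type"])
        for u, v, data in sorted(G.edges(data=True)):
            writer.writerow([u, v, data.get("weight", 1), "undirected"])
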