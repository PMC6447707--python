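"""Helper/beneficiary classification from gene content, and the
cross-feeding interaction network.

The rules encode the Black Queen-style division of labor around the
cellodextrin public good: a taxon that carries an endoglucanase gene
produces extracellular cellodextrins (helper); a taxon without
endoglucanase but with downstream assimilation enzymes (beta-glucosidase,
6-phospho-beta-glucosidase, or cellobiose phosphorylase) cross-feeds on
them (beneficiary).  Because only two bacterial cellodextrin transporter
families are characterized, a helper or beneficiary lacking both is
flagged ``unclassified_possible`` rather than demoted: it plausibly
encodes an uncharacterized transporter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .references import DOWNSTREAM_FEATURES, EC_TO_FEATURE, ROLE_FEATURES

ROLES = ("helper", "beneficiary", "non_participant")
POOL_NODE = "cellodextrin_pool"
INHIBITION_TARGET = "endoglucanase_expression"


class RoleError(ValueError):
    pass


# ---------------------------------------------------------------------------
# gene-content matrix

def build_gene_content_matrix(annotations: pd.DataFrame, grouping: str = "genus",
                              groups: list[str] | None = None) -> pd.DataFrame:
    """Taxon/bin x role-feature boolean presence matrix.

    A feature is present in a group iff at least one gene of the group
    carries the corresponding EC or transporter label.  ``grouping``
    names the annotation column to group by ("genus" or a bin column);
    ``groups`` may force rows (all-false with a warning when empty).
    """
    rows: dict[str, dict[str, bool]] = {}
    wanted = list(groups) if groups else []
    for g in wanted:
        rows[g] = {f: False for f in ROLE_FEATURES}
    if len(annotations):
        for _, row in annotations.iterrows():
            group = row[grouping]
            if group in ("unassigned", "", None) and not groups:
                continue
            if group not in rows:
                if groups:
                    continue
                rows[group] = {f: False for f in ROLE_FEATURES}
            for ec in str(row.get("ec_labels") or "").split(","):
                feat = EC_TO_FEATURE.get(ec)
                if feat:
                    rows[group][feat] = True
            labels = str(row.get("transporter_labels") or "")
            if any(t.startswith("PTS_") for t in labels.split(",")):
                rows[group]["pts_cel"] = True
            if any(t.startswith("ABC_") for t in labels.split(",")):
                rows[group]["abc_ceb"] = True
    for g, feats in rows.items():
        if not any(feats.values()):
            warnings.warn(f"group {g!r} has no role-feature genes")
    matrix = pd.DataFrame.from_dict(rows, orient="index").astype(bool)
    if matrix.empty:
        matrix = pd.DataFrame(columns=list(ROLE_FEATURES)).astype(bool)
    return matrix[list(ROLE_FEATURES)].sort_index()


# ---------------------------------------------------------------------------
# role classification

@dataclass
class RoleAssignment:
    taxon: str
    role: str
    transporter_status: str  # classified | unclassified_possible
    evidence: tuple[str, ...] = ()
    warnings: tuple[str, ...] = ()


def classify_roles(matrix: pd.DataFrame) -> list[RoleAssignment]:
    """Row-wise helper/beneficiary/non-participant calls.

    helper: endoglucanase present (an endoglucanase-only row is still a
    helper, with a no-assimilation warning); beneficiary: no
    endoglucanase but >= 1 downstream assimilation enzyme; otherwise
    non-participant.  Transporter absence in a helper/beneficiary sets
    ``unclassified_possible`` instead of changing the role.
    """
    missing = [f for f in ROLE_FEATURES if f not in matrix.columns]
    if missing:
        raise RoleError(f"matrix lacks features: {missing}")
    out = []
    for taxon, row in matrix.iterrows():
        evidence = tuple(f for f in ROLE_FEATURES if bool(row[f]))
        downstream = any(row[f] for f in DOWNSTREAM_FEATURES)
        warns: tuple[str, ...] = ()
        if row["endoglucanase"]:
            role = "helper"
            if not downstream:
                warns = ("no-assimilation",)
        elif downstream:
            role = "beneficiary"
        else:
            role = "non_participant"
        if role in ("helper", "beneficiary") and not (row["pts_cel"] or row["abc_ceb"]):
            status = "unclassified_possible"
        else:
            status = "classified"
        out.append(RoleAssignment(str(taxon), role, status, evidence, warns))
    return out


# ---------------------------------------------------------------------------
# interaction network

def build_network(assignments: list[RoleAssignment]) -> nx.DiGraph:
    """Directed cross-feeding network around the cellodextrin pool.

    Helpers produce into the pool; helpers and beneficiaries with
    downstream enzymes consume from it; when any helper exists the pool
    carries one inhibition edge back onto endoglucanase expression
    (product inhibition of the cellulolytic step).
    """
    if not assignments:
        raise RoleError("no assignments")
    g = nx.DiGraph()
    g.add_node(POOL_NODE, kind="pool")
    for a in assignments:
        g.add_node(a.taxon, kind="taxon", role=a.role,
                   transporter_status=a.transporter_status)
        if a.role == "helper":
            g.add_edge(a.taxon, POOL_NODE, type="produces")
        if a.role in ("helper", "beneficiary") and (
            set(a.evidence) & set(DOWNSTREAM_FEATURES)
        ):
            g.add_edge(POOL_NODE, a.taxon, type="consumes")
    if any(a.role == "helper" for a in assignments):
        g.add_node(INHIBITION_TARGET, kind="process")
        g.add_edge(POOL_NODE, INHIBITION_TARGET, type="inhibits")
    return g


def network_edge_list(g: nx.DiGraph) -> pd.DataFrame:
    rows = [{"source": u, "target": v, "type": d["type"]}
            for u, v, d in g.edges(data=True)]
    return pd.DataFrame(rows, columns=["source", "target", "type"])


# ---------------------------------------------------------------------------
# validation against simulator truth

def role_recovery(assignments: list[RoleAssignment],
                  truth: dict[str, str]) -> tuple[pd.DataFrame, float]:
    """3x3 role confusion matrix and accuracy against truth labels."""
    missing = [a.taxon for a in assignments if a.taxon not in truth]
    if missing:
        raise RoleError(f"truth lacks taxa: {missing}")
    cm = pd.DataFrame(0, index=list(ROLES), columns=list(ROLES))
    for a in assignments:
        cm.loc[truth[a.taxon], a.role] += 1
    total = cm.to_numpy().sum()
    accuracy = float(cm.to_numpy().trace() / total) if total else 0.0
    return cm, accuracy


# ---------------------------------------------------------------------------
# worked example: the six dominant genera

def dominant_genus_gene_content() -> pd.DataFrame:
    """Presence/absence gene-content rows for the six dominant genera of
    a cellulose-rich alkaline paper-pulp community.

    Clostridium carries the full pathway with PTS transporters;
    Paludibacter carries endoglucanase, beta-glucosidase and cellobiose
    phosphorylase but no characterized transporter; Cloacibacterium only
    the downstream glucosidases; Exiguobacterium, Acetivibrio and
    Tolumonas the downstream glucosidases plus PTS transporters.
    """
    rows = {
        "Clostridium": dict(endoglucanase=True, beta_glucosidase=True,
                            six_phospho_beta_glucosidase=True,
                            cellobiose_phosphorylase=False,
                            pts_cel=True, abc_ceb=False),
        "Paludibacter": dict(endoglucanase=True, beta_glucosidase=True,
                             six_phospho_beta_glucosidase=False,
                             cellobiose_phosphorylase=True,
                             pts_cel=False, abc_ceb=False),
        "Cloacibacterium": dict(endoglucanase=False, beta_glucosidase=True,
                                six_phospho_beta_glucosidase=True,
                                cellobiose_phosphorylase=False,
                                pts_cel=False, abc_ceb=False),
        "Exiguobacterium": dict(endoglucanase=False, beta_glucosidase=True,
                                six_phospho_beta_glucosidase=True,
                                cellobiose_phosphorylase=False,
                                pts_cel=True, abc_ceb=False),
        "Acetivibrio": dict(endoglucanase=False, beta_glucosidase=True,
                            six_phospho_beta_glucosidase=True,
                            cellobiose_phosphorylase=False,
                            pts_cel=True, abc_ceb=False),
        "Tolumonas": dict(endoglucanase=False, beta_glucosidase=True,
                          six_phospho_beta_glucosidase=True,
                          cellobiose_phosphorylase=False,
                          pts_cel=True, abc_ceb=False),
    }
    return pd.DataFrame.from_dict(rows, orient="index")[list(ROLE_FEATURES)]
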