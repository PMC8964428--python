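"""Drug-pathway reversal scoring and the drug-pathway-cancer triplet network.

Each drug is represented by one or more perturbation instances (a cell line
treated with the drug vs its untreated control), each reduced to a ranked
gene list. The enrichment (NES) of a pathway's gene set in an instance
ranking measures whether the drug pushes the pathway up or down; the
perturbation NES (PNS) of a drug for a pathway is the mean instance NES.
The prescription score pairs a pathway's dysregulation in a cancer (CNS)
with the drug's PNS for the same pathway:

    PS = CNS - PNS   (signed)

A large positive PS marks a drug that depletes an enriched pathway; a large
negative PS a drug that restores a depleted one. Candidate triplets
(drug, pathway, cancer) require the pathway to be prognostic in that cancer
(log-rank p < 0.001) and strongly dysregulated (|CNS| > 1.5, strict); drugs
are ranked by |PS| and labeled reversers when the PNS sign opposes the CNS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import ScoreMatrix, ValidationError
from .enrichment import RankedList, enrichment_score, nes_and_significance
from .survival import PrognosticPathway


@dataclass
class PerturbationProfile:
    """One drug instance: a treated-vs-control differential gene ranking."""

    drug_id: str
    instance_id: str
    ranked_genes: RankedList


@dataclass
class PrescriptionScore:
    drug: str
    pathway: str
    cancer: str
    cns_value: float
    pns_value: float
    ps: float
    effect: str  # "Enrichment" if CNS > 0 else "Depletion"


@dataclass
class Triplet:
    drug: str
    pathway: str
    cancer: str
    ps: float
    cns: float
    pns: float
    logrank_p: float
    is_reverser: bool = True
    passed_filters: dict = field(default_factory=dict)


def drug_pathway_nes(
    profile: PerturbationProfile,
    gene_set,
    n_perm: int = 1000,
    seed: int = 0,
) -> float:
    """NES of a pathway gene set in one instance ranking (gene-set null)."""
    es = enrichment_score(profile.ranked_genes, gene_set)
    res = nes_and_significance(es, profile.ranked_genes, gene_set, n_perm, seed)
    return res.nes


def aggregate_instances(per_instance_nes) -> float:
    """Drug-level PNS: the arithmetic mean of its instance NES values."""
    values = np.asarray(list(per_instance_nes), dtype=float)
    if values.size == 0:
        raise ValidationError("no instance NES values to aggregate")
    return float(values.mean())


def compute_pns(
    profiles: list[PerturbationProfile],
    sets,
    n_perm: int = 1000,
    seed: int = 0,
) -> ScoreMatrix:
    """Drugs x pathways PNS matrix from a perturbation library.

    Instances of the same drug are scored independently (each against its own
    ranking, with its own gene-set permutation null) and averaged.
    """
    rng = np.random.default_rng(seed)
    drugs: dict[str, list[PerturbationProfile]] = {}
    for p in profiles:
        drugs.setdefault(p.drug_id, []).append(p)
    names = sets.names() if hasattr(sets, "names") else list(sets)
    get = sets.sets.__getitem__ if hasattr(sets, "sets") else sets.__getitem__
    pns = np.empty((len(drugs), len(names)))
    for i, (_, instances) in enumerate(drugs.items()):
        for j, name in enumerate(names):
            per_instance = [
                drug_pathway_nes(
                    inst, get(name), n_perm, seed=rng.integers(0, 2**31 - 1)
                )
                for inst in instances
            ]
            pns[i, j] = aggregate_instances(per_instance)
    return ScoreMatrix(list(drugs), names, pns)


def prescription_score(
    cns_value: float,
    pns_value: float,
    drug: str = "",
    pathway: str = "",
    cancer: str = "",
) -> PrescriptionScore:
    """Signed prescription score PS = CNS - PNS for one drug-pathway-cancer.

    The effect label reflects the pathway's dysregulation (Enrichment when
    CNS > 0, Depletion otherwise); reversal potency ranks by |PS| within an
    effect class. Swapping the two inputs negates PS.
    """
    if not (np.isfinite(cns_value) and np.isfinite(pns_value)):
        raise ValidationError("CNS and PNS must be finite")
    ps = cns_value - pns_value
    effect = "Enrichment" if cns_value > 0 else "Depletion"
    return PrescriptionScore(drug, pathway, cancer, cns_value, pns_value, ps, effect)


def build_triplet_network(
    cns: ScoreMatrix,
    pns: ScoreMatrix,
    prognostic: list[PrognosticPathway],
    cns_abs_threshold: float = 1.5,
    top_k: int | None = None,
    reversers_only: bool = False,
) -> list[Triplet]:
    """Assemble the filtered drug-pathway-cancer network.

    For every (cancer, pathway) where the pathway is prognostic in that
    cancer and |CNS| > ``cns_abs_threshold`` (strict), one candidate triplet
    per drug scoring that pathway is formed with PS = CNS - PNS. Candidates
    whose PS opposes the dysregulation (sign(PS) = sign(CNS)) are kept,
    ranked by |PS| (descending) within each (cancer, pathway); a drug whose
    PNS sign actually opposes the CNS sign is flagged ``is_reverser`` while
    same-sign-but-smaller PNS drugs rank low and are not flagged.
    ``top_k`` truncates each (cancer, pathway) group.
    """
    prog_index: dict[tuple[str, str], PrognosticPathway] = {
        (r.cancer, r.pathway): r for r in prognostic
    }
    shared = [p for p in cns.row_ids if p in set(pns.col_ids)]
    triplets: list[Triplet] = []
    for (cancer, pathway), rec in sorted(prog_index.items()):
        if pathway not in shared or cancer not in cns.col_ids:
            continue
        cns_val = cns.value(pathway, cancer)
        if not np.isfinite(cns_val) or abs(cns_val) <= cns_abs_threshold:
            continue
        j = pns.col_ids.index(pathway)
        group: list[Triplet] = []
        for i, drug in enumerate(pns.row_ids):
            pns_val = float(pns.nes[i, j])
            if not np.isfinite(pns_val):
                continue
            score = prescription_score(cns_val, pns_val, drug, pathway, cancer)
            if np.sign(score.ps) != np.sign(cns_val):
                continue  # drug pushes the pathway further in the same direction
            is_rev = bool(np.sign(pns_val) == -np.sign(cns_val) and pns_val != 0)
            if reversers_only and not is_rev:
                continue
            group.append(
                Triplet(
                    drug, pathway, cancer, score.ps, cns_val, pns_val, rec.p,
                    is_reverser=is_rev,
                    passed_filters={
                        "prognostic_p": rec.p,
                        "cns_abs_threshold": cns_abs_threshold,
                    },
                )
            )
        group.sort(key=lambda t: -abs(t.ps))
        if top_k is not None:
            group = group[:top_k]
        triplets.extend(group)
    return triplets
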