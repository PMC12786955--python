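"""Synthetic atom-mapped hydrogenation reactions with planted condition rules.

Real condition-annotated reaction corpora are proprietary, so this module
generates a structurally analogous dataset: mapped H₂-mediated
transformations (alkene/alkyne reduction, nitro reduction, benzyl-ether
hydrogenolysis, imine reduction) over randomized alkyl/aryl scaffolds, each
paired with conditions drawn from a template-specific categorical rule. A
*transformation* is a reactant→product pair; a *reaction* is a
transformation plus one recorded condition — one transformation may carry
several recorded conditions.

The planted signal is simple by design: the functional group being reduced
determines the condition distribution (e.g. alkynes go to Lindlar-type
poisoned catalysts, benzyl ethers to Pd(OH)₂ with acid), with a configurable
probability of drawing from the global marginal instead (label noise) and a
configurable fraction of records with unknown temperature/pressure. A Bayes
oracle that reads the planted rules gives the performance ceiling any model
can reach on this data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from rdkit import Chem

from .conditions import (UNKNOWN, ConditionRecord, ConditionScheme,
                         ConditionVector, encode, make_scheme)
from .inference import RankedConditionList

__all__ = ["GeneratorSpec", "ReactionRecord", "generate_dataset",
           "split_train_test", "apply_curation_filters", "oracle_rank",
           "default_rule_table", "TEMPLATES"]

TEMPLATES = ("alkene_to_alkane", "alkyne_to_alkene", "nitro_to_amine",
             "benzyl_ether_hydrogenolysis", "imine_to_amine")

# representative T (°C) / P (atm) values safely inside their bins
_T_COOL, _T_AMBIENT, _T_HEAT = 5.0, 25.0, 60.0
_P_LOW, _P_MED, _P_HIGH = 1.0, 50.0, 150.0


def default_rule_table() -> dict[str, list[tuple[float, ConditionRecord]]]:
    """Template → categorical distribution over condition records.

    Catalyst names refer to the stock scheme-S vocabulary; probabilities sum
    to 1 per template. The assignments mirror bench practice: plain alkenes
    reduce over Pd/C at ambient conditions, alkynes need a poisoned
    (Lindlar-type) catalyst to stop at the alkene, nitro groups tolerate
    harsher Raney-Ni or acidic Pd conditions, benzyl ethers cleave over
    Pearlman's catalyst with acid, imines reduce over PtO₂ or Pd/C with base.
    """
    R = ConditionRecord
    return {
        "alkene_to_alkane": [
            (0.50, R("Pd/C", frozenset(), _T_AMBIENT, _P_LOW)),
            (0.25, R("PtO2", frozenset(), _T_AMBIENT, _P_MED)),
            (0.15, R("Raney Ni", frozenset(), _T_HEAT, _P_MED)),
            (0.10, R("Rh/C", frozenset(), _T_AMBIENT, _P_MED)),
        ],
        "alkyne_to_alkene": [
            (0.70, R("Lindlar", frozenset({"catalytic poison"}), _T_AMBIENT, _P_LOW)),
            (0.30, R("Pd/C", frozenset({"catalytic poison"}), _T_COOL, _P_LOW)),
        ],
        "nitro_to_amine": [
            (0.45, R("Raney Ni", frozenset(), _T_HEAT, _P_MED)),
            (0.30, R("Pd/C", frozenset({"acid"}), _T_AMBIENT, _P_LOW)),
            (0.15, R("PtO2", frozenset({"acid"}), _T_AMBIENT, _P_MED)),
            (0.10, R("Ni", frozenset(), _T_HEAT, _P_MED)),
        ],
        "benzyl_ether_hydrogenolysis": [
            (0.60, R("Pd(OH)2/C", frozenset({"acid"}), _T_AMBIENT, _P_MED)),
            (0.40, R("Pd/C", frozenset(), _T_AMBIENT, _P_LOW)),
        ],
        "imine_to_amine": [
            (0.45, R("PtO2", frozenset(), _T_AMBIENT, _P_MED)),
            (0.30, R("Pd/C", frozenset({"base"}), _T_AMBIENT, _P_LOW)),
            (0.15, R("Ru/C", frozenset(), _T_HEAT, _P_HIGH)),
            (0.10, R("Raney Ni", frozenset(), _T_HEAT, _P_MED)),
        ],
    }


@dataclass
class GeneratorSpec:
    """Study conditions for the synthetic corpus.

    `conditions_per_transformation` gives the probability of each count
    (index 0 → one condition, index 1 → two, …); `noise_rate` is the chance a
    record's condition is drawn from the global marginal rather than its
    template rule; `missing_tp_rate` is the chance a record loses its T/P
    annotation (requires a scheme that allows unknown T/P); `dirty_rate`
    injects curation-test defects (duplicates and acid+base conflicts).
    """

    scheme: ConditionScheme = field(default_factory=lambda: make_scheme("S"))
    rule_table: dict[str, list[tuple[float, ConditionRecord]]] = field(
        default_factory=default_rule_table)
    templates: tuple[str, ...] = TEMPLATES
    n_transformations: int = 2000
    conditions_per_transformation: tuple[float, ...] = (0.7, 0.3)
    noise_rate: float = 0.1
    missing_tp_rate: float = 0.0
    dirty_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name, rules in self.rule_table.items():
            total = sum(p for p, _ in rules)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"rule probabilities for {name!r} sum to {total}")
        if self.missing_tp_rate > 0 and not self.scheme.allow_unknown_tp:
            raise ValueError("missing_tp_rate needs a scheme that allows unknown T/P")

    def marginal(self) -> list[tuple[float, ConditionRecord]]:
        """Global condition marginal under a uniform template mix."""
        acc: dict[ConditionRecord, float] = {}
        w = 1.0 / len(self.templates)
        for t in self.templates:
            for p, rec in self.rule_table[t]:
                acc[rec] = acc.get(rec, 0.0) + w * p
        return [(p, rec) for rec, p in acc.items()]


@dataclass
class ReactionRecord:
    """One reaction: a mapped transformation plus one recorded condition."""

    smiles: str
    transformation_key: str
    template: str
    record: ConditionRecord
    condition: ConditionVector | None     # None when the record is invalid
    tp_mask: tuple[bool, bool] = (True, True)

    @property
    def is_complete(self) -> bool:
        return self.tp_mask[0] and self.tp_mask[1]


# ----------------------------------------------------------------------
# scaffold construction
# ----------------------------------------------------------------------
_TERMINALS = ("", "c1ccccc1", "OC", "C(F)(F)F")


def _random_alkyl(rng: np.random.Generator, max_len: int = 4) -> str:
    """Random branched alkyl SMILES fragment (first atom = attachment)."""
    n = int(rng.integers(1, max_len + 1))
    parts = []
    for i in range(n):
        parts.append("C")
        if i > 0 and rng.random() < 0.25:
            parts.append("(C)")
    if rng.random() < 0.35:
        parts.append(_TERMINALS[int(rng.integers(0, len(_TERMINALS)))])
    return "".join(parts)


def _attach(rw: Chem.RWMol, attach_idx: int, fragment_smiles: str) -> Chem.RWMol:
    frag = Chem.MolFromSmiles(fragment_smiles)
    if frag is None:
        raise ValueError(f"template rendering failure: bad fragment {fragment_smiles!r}")
    offset = rw.GetNumAtoms()
    combined = Chem.RWMol(Chem.CombineMols(rw.GetMol(), frag))
    combined.AddBond(attach_idx, offset, Chem.BondType.SINGLE)
    return combined


def _render(template: str, rng: np.random.Generator) -> tuple[str, str]:
    """Build (mapped reaction SMILES, unmapped transformation key)."""
    if template == "alkene_to_alkane":
        core, sites, edit = "C=C", (0, 1), ("bond", 0, 1, Chem.BondType.SINGLE)
    elif template == "alkyne_to_alkene":
        core, sites, edit = "C#C", (0, 1), ("bond", 0, 1, Chem.BondType.DOUBLE)
    elif template == "nitro_to_amine":
        core, sites, edit = "[N+](=O)[O-]", (0,), ("nitro", 0, 1, 2)
    elif template == "benzyl_ether_hydrogenolysis":
        core, sites, edit = "OCc1ccccc1", (0,), ("cleave", 0, 1)
    elif template == "imine_to_amine":
        core, sites, edit = "C=N", (0, 1), ("bond", 0, 1, Chem.BondType.SINGLE)
    else:
        raise ValueError(f"unknown template {template!r}")

    rw = Chem.RWMol(Chem.MolFromSmiles(core))
    for site in sites:
        rw = _attach(rw, site, _random_alkyl(rng))
    reactant = rw.GetMol()
    Chem.SanitizeMol(reactant)
    for atom in reactant.GetAtoms():
        atom.SetAtomMapNum(atom.GetIdx() + 1)

    product = Chem.RWMol(reactant)
    kind = edit[0]
    if kind == "bond":
        product.GetBondBetweenAtoms(edit[1], edit[2]).SetBondType(edit[3])
    elif kind == "nitro":
        n_idx, o1, o2 = edit[1:]
        nitrogen = product.GetAtomWithIdx(n_idx)
        nitrogen.SetFormalCharge(0)
        nitrogen.SetNoImplicit(False)    # freed valences become amine Hs
        for idx in sorted((o1, o2), reverse=True):
            product.RemoveAtom(idx)
    elif kind == "cleave":
        product.RemoveBond(edit[1], edit[2])
    product_mol = product.GetMol()
    Chem.SanitizeMol(product_mol)

    r_smi = Chem.MolToSmiles(reactant)
    p_smi = Chem.MolToSmiles(product_mol)
    rxn = f"{r_smi}.[H][H]>>{p_smi}"

    plain_r = Chem.Mol(reactant)
    plain_p = Chem.Mol(product_mol)
    for mol in (plain_r, plain_p):
        for atom in mol.GetAtoms():
            atom.SetAtomMapNum(0)
    key = f"{Chem.MolToSmiles(plain_r)}>>{Chem.MolToSmiles(plain_p)}"
    return rxn, key


# ----------------------------------------------------------------------
def _draw(rules: list[tuple[float, ConditionRecord]],
          rng: np.random.Generator) -> ConditionRecord:
    probs = np.array([p for p, _ in rules])
    idx = rng.choice(len(rules), p=probs / probs.sum())
    return rules[idx][1]


def generate_dataset(spec: GeneratorSpec) -> list[ReactionRecord]:
    """Render the corpus: deterministic given ``spec.seed``.

    Transformations are unique reactant→product pairs (scaffold collisions
    are retried); each carries 1+ recorded conditions per the configured
    count distribution, with noise and missing-T/P effects applied per
    record. Dirty injection (``dirty_rate``) appends exact duplicates and
    acid+base-conflicted records for exercising the curation filters.
    """
    rng = np.random.default_rng(spec.seed)
    records: list[ReactionRecord] = []
    seen_keys: set[str] = set()
    counts = np.array(spec.conditions_per_transformation)
    marginal = spec.marginal()
    made = 0
    attempts = 0
    while made < spec.n_transformations:
        attempts += 1
        if attempts > 50 * spec.n_transformations:
            raise RuntimeError("scaffold space exhausted; lower n_transformations")
        template = spec.templates[int(rng.integers(0, len(spec.templates)))]
        try:
            rxn, key = _render(template, rng)
        except Exception as exc:  # pragma: no cover - rendering is total
            raise RuntimeError(f"template rendering failure in {template}: {exc}")
        if key in seen_keys:
            continue
        seen_keys.add(key)
        made += 1
        n_cond = 1 + int(rng.choice(len(counts), p=counts / counts.sum()))
        drawn: set[ConditionRecord] = set()
        for _ in range(n_cond):
            rules = marginal if rng.random() < spec.noise_rate else spec.rule_table[template]
            rec = _draw(rules, rng)
            if rec in drawn:
                continue
            drawn.add(rec)
            if spec.missing_tp_rate > 0 and rng.random() < spec.missing_tp_rate:
                which = rng.integers(0, 3)  # 0: T, 1: P, 2: both
                if which in (0, 2):
                    rec = replace(rec, temperature=UNKNOWN)
                if which in (1, 2):
                    rec = replace(rec, pressure=UNKNOWN)
            vec = encode(rec, spec.scheme)
            records.append(ReactionRecord(
                smiles=rxn, transformation_key=key, template=template,
                record=rec, condition=vec,
                tp_mask=(not vec.temp_unknown, not vec.pressure_unknown)))
        if spec.dirty_rate > 0 and rng.random() < spec.dirty_rate:
            last = records[-1]
            if rng.random() < 0.5:
                records.append(last)  # exact duplicate
            else:
                bad = replace(last.record,
                              additives=frozenset({"acid", "base"}))
                records.append(ReactionRecord(
                    smiles=rxn, transformation_key=key, template=template,
                    record=bad, condition=None, tp_mask=last.tp_mask))
    return records


def split_train_test(records: list[ReactionRecord], test_fraction: float = 0.15,
                     seed: int = 0) -> tuple[list[ReactionRecord], list[ReactionRecord]]:
    """Split by transformation; the test side only takes transformations with
    a single recorded condition and fully known T/P, and no transformation
    appears in both sides."""
    by_key: dict[str, list[ReactionRecord]] = {}
    for r in records:
        by_key.setdefault(r.transformation_key, []).append(r)
    eligible = [k for k, v in by_key.items()
                if len(v) == 1 and v[0].is_complete and v[0].condition is not None]
    n_test = int(round(test_fraction * len(by_key)))
    if n_test > len(eligible):
        raise ValueError(
            f"cannot fill test fraction {test_fraction}: only {len(eligible)} "
            f"single-condition complete transformations available")
    rng = np.random.default_rng(seed)
    test_keys = set(rng.choice(np.array(sorted(eligible)), size=n_test, replace=False))
    train = [r for r in records if r.transformation_key not in test_keys]
    test = [r for r in records if r.transformation_key in test_keys]
    return train, test


def apply_curation_filters(records: list[ReactionRecord],
                           scheme: ConditionScheme
                           ) -> tuple[list[ReactionRecord], list[tuple[ReactionRecord, str]]]:
    """Drop invalid records and collapse exact duplicates.

    Rejection reasons: ``acid_base_conflict`` (both roles recorded under a
    forbidding scheme), ``multiple_catalysts``, ``duplicate`` (same
    transformation and condition already kept).
    """
    kept: list[ReactionRecord] = []
    rejected: list[tuple[ReactionRecord, str]] = []
    seen: set[tuple] = set()
    for r in records:
        adds = r.record.additives
        if (scheme.forbid_acid_base_together
                and any(a.startswith("acid") for a in adds)
                and any(a.startswith("base") for a in adds)):
            rejected.append((r, "acid_base_conflict"))
            continue
        if isinstance(r.record.catalyst, (tuple, list)) and len(r.record.catalyst) > 1:
            rejected.append((r, "multiple_catalysts"))
            continue
        key = (r.transformation_key, r.record)
        if key in seen:
            rejected.append((r, "duplicate"))
            continue
        seen.add(key)
        kept.append(r)
    return kept, rejected


def oracle_rank(template: str, spec: GeneratorSpec,
                query_id: str = "") -> RankedConditionList:
    """Bayes-optimal ranking given the planted rules.

    Ranks complete conditions by their true generative probability
    (1−noise)·rule(template) + noise·marginal — the ceiling for any model
    trained on this corpus.
    """
    probs: dict[ConditionRecord, float] = {}
    for p, rec in spec.rule_table[template]:
        probs[rec] = probs.get(rec, 0.0) + (1.0 - spec.noise_rate) * p
    for p, rec in spec.marginal():
        probs[rec] = probs.get(rec, 0.0) + spec.noise_rate * p
    scored = [(prob, encode(rec, spec.scheme)) for rec, prob in probs.items()]
    scored.sort(key=lambda t: (-t[0], t[1].sort_key()))
    entries = [(vec, max(1, int(round(1000 * prob)))) for prob, vec in scored]
    return RankedConditionList(entries=entries, query_id=query_id,
                               total_draws=1000)
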