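"""Negative design: rule-based exclusion of undesirable screening hits.

Re-expresses the usual post-screening triage — PAINS substructure alerts,
physicochemical drug-likeness windows, promiscuity scores and aggregation
flags — as a local, fully configurable rule engine.  Aggregation and
promiscuity arrive as per-compound annotations (e.g. imported CSV columns);
substructure and property rules are evaluated from SMILES via RDKit when a
structure is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "CompoundEntry",
    "FilterRule",
    "FilterVerdict",
    "default_ruleset",
    "default_property_windows",
    "load_ruleset_yaml",
    "apply_filters",
    "survivors",
]

logger = logging.getLogger(__name__)

PASS, FAIL, NOT_EVALUABLE = "pass", "fail", "not_evaluable"

#: default drug-likeness windows: property -> (min, max), annotation-overridable
DEFAULT_PROPERTY_WINDOWS: dict[str, tuple[float, float]] = {
    "MW": (100.0, 600.0),
    "cLogP": (-3.0, 6.0),
    "HBD": (0.0, 5.0),
    "HBA": (0.0, 10.0),
    "RotB": (0.0, 11.0),
}

#: promiscuity score at or above which a compound is excluded
PSCORE_CUTOFF = 300.0


@dataclass
class CompoundEntry:
    """A screening hit: optional SMILES plus free-form annotations
    (e.g. ``pScore``, ``aggregator``, precomputed properties)."""

    compound_id: str
    smiles: Optional[str] = None
    annotations: dict = field(default_factory=dict)


@dataclass
class FilterRule:
    """One exclusion rule.

    ``kind`` ∈ {``substructure_alert``, ``property_window``,
    ``annotation_threshold``, ``annotation_flag``}; ``payload`` depends on
    the kind — a SMARTS pattern / catalogue tag, a ``(property, min, max)``
    triple, an ``(annotation key, threshold, comparator)`` triple with
    comparator in {>=, >, <=, <}, or a bare annotation key whose truthiness
    fails the compound.
    """

    name: str
    kind: str
    payload: object

    _KINDS = ("substructure_alert", "property_window", "annotation_threshold", "annotation_flag")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown rule kind {self.kind!r}")
        if self.kind == "property_window":
            prop, lo, hi = self.payload  # unpack to validate shape
            if not lo <= hi:
                raise ValueError(f"empty window for {prop}")
        elif self.kind == "annotation_threshold":
            _, _, comparator = self.payload
            if comparator not in (">=", ">", "<=", "<"):
                raise ValueError(f"bad comparator {comparator!r}")


@dataclass
class FilterVerdict:
    """Per-rule outcomes for one compound; overall pass iff no rule failed
    (``not_evaluable`` counts as a failure only in strict mode)."""

    compound_id: str
    outcomes: dict[str, str]
    overall: bool
    reasons: list[str] = field(default_factory=list)


def default_property_windows() -> dict[str, tuple[float, float]]:
    return dict(DEFAULT_PROPERTY_WINDOWS)


def default_ruleset(property_windows: dict[str, tuple[float, float]] | None = None) -> list[FilterRule]:
    """The shipped ruleset: PAINS families A/B/C, the drug-likeness property
    windows, promiscuity ``pScore >= 300`` and the aggregator flag."""
    windows = property_windows if property_windows is not None else default_property_windows()
    rules = [FilterRule("pains", "substructure_alert", "PAINS")]
    for prop, (lo, hi) in windows.items():
        rules.append(FilterRule(f"window_{prop}", "property_window", (prop, lo, hi)))
    rules.append(FilterRule("promiscuity", "annotation_threshold", ("pScore", PSCORE_CUTOFF, ">=")))
    rules.append(FilterRule("aggregator", "annotation_flag", "aggregator"))
    return rules


def load_ruleset_yaml(path) -> list[FilterRule]:
    """Load a ruleset from YAML: a list of mappings with ``name``, ``kind``
    and ``payload`` (a list payload is converted to the tuple the kind
    expects)."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    rules = []
    for item in raw:
        payload = item["payload"]
        if isinstance(payload, list):
            payload = tuple(payload)
        rules.append(FilterRule(item["name"], item["kind"], payload))
    return rules


_PAINS_CATALOG = None


def _pains_catalog():
    global _PAINS_CATALOG
    if _PAINS_CATALOG is None:
        from rdkit.Chem.FilterCatalog import FilterCatalog, FilterCatalogParams

        params = FilterCatalogParams()
        params.AddCatalog(FilterCatalogParams.FilterCatalogs.PAINS)
        _PAINS_CATALOG = FilterCatalog(params)
    return _PAINS_CATALOG


def _parse_mol(smiles: str):
    from rdkit import Chem

    return Chem.MolFromSmiles(smiles)


def _rdkit_property(mol, prop: str) -> float:
    from rdkit.Chem import Crippen, Descriptors, Lipinski

    if prop == "MW":
        return Descriptors.MolWt(mol)
    if prop == "cLogP":
        return Crippen.MolLogP(mol)
    if prop == "HBD":
        return float(Lipinski.NumHDonors(mol))
    if prop == "HBA":
        return float(Lipinski.NumHAcceptors(mol))
    if prop == "RotB":
        return float(Lipinski.NumRotatableBonds(mol))
    raise KeyError(f"no RDKit calculator for property {prop!r}")


def _eval_rule(rule: FilterRule, entry: CompoundEntry, mol) -> tuple[str, str | None]:
    """Returns (outcome, reason)."""
    if rule.kind == "substructure_alert":
        if mol is None:
            return NOT_EVALUABLE, f"{rule.name}: structure unavailable/unparsable"
        if rule.payload == "PAINS":
            catalog = _pains_catalog()
            match = catalog.GetFirstMatch(mol)
            if match is not None:
                return FAIL, f"{rule.name}: {match.GetDescription()}"
            return PASS, None
        from rdkit import Chem

        pattern = Chem.MolFromSmarts(str(rule.payload))
        if pattern is None:
            return NOT_EVALUABLE, f"{rule.name}: bad SMARTS"
        return (FAIL, f"{rule.name}: SMARTS match") if mol.HasSubstructMatch(pattern) else (PASS, None)

    if rule.kind == "property_window":
        prop, lo, hi = rule.payload
        value = entry.annotations.get(prop)
        if value is None:
            if mol is None:
                return NOT_EVALUABLE, f"{rule.name}: no structure and no {prop} annotation"
            try:
                value = _rdkit_property(mol, prop)
            except KeyError:
                return NOT_EVALUABLE, f"{rule.name}: {prop} not computable"
        value = float(value)
        if lo <= value <= hi:
            return PASS, None
        return FAIL, f"{rule.name}: {prop}={value:g} outside [{lo:g}, {hi:g}]"

    if rule.kind == "annotation_threshold":
        key, threshold, comparator = rule.payload
        value = entry.annotations.get(key)
        if value is None:
            return NOT_EVALUABLE, f"{rule.name}: missing annotation {key!r}"
        value = float(value)
        hit = {
            ">=": value >= threshold,
            ">": value > threshold,
            "<=": value <= threshold,
            "<": value < threshold,
        }[comparator]
        return (FAIL, f"{rule.name}: {key}={value:g} {comparator} {threshold:g}") if hit else (PASS, None)

    # annotation_flag
    key = str(rule.payload)
    value = entry.annotations.get(key)
    if value is None:
        return NOT_EVALUABLE, f"{rule.name}: missing annotation {key!r}"
    return (FAIL, f"{rule.name}: flagged {key}") if bool(value) else (PASS, None)


def apply_filters(
    compounds: list[CompoundEntry],
    rules: list[FilterRule] | None = None,
    strict: bool = False,
) -> tuple[list[FilterVerdict], dict[str, int]]:
    """Evaluate every rule on every compound.

    Verdicts are independent per compound.  A compound passes overall iff no
    rule failed; rules that cannot be evaluated (missing structure or
    annotation) are recorded as ``not_evaluable`` and, unless ``strict`` is
    set, do not fail the compound.  Returns the verdict list plus per-rule
    failure counts for Venn-style reporting.
    """
    if rules is None:
        rules = default_ruleset()
    verdicts: list[FilterVerdict] = []
    counts: dict[str, int] = {rule.name: 0 for rule in rules}
    for entry in compounds:
        mol = _parse_mol(entry.smiles) if entry.smiles else None
        if entry.smiles and mol is None:
            logger.warning("unparsable SMILES for %s", entry.compound_id)
        outcomes: dict[str, str] = {}
        reasons: list[str] = []
        for rule in rules:
            outcome, reason = _eval_rule(rule, entry, mol)
            outcomes[rule.name] = outcome
            if reason:
                reasons.append(reason)
            if outcome == FAIL:
                counts[rule.name] += 1
        bad = {FAIL, NOT_EVALUABLE} if strict else {FAIL}
        overall = not any(o in bad for o in outcomes.values())
        verdicts.append(FilterVerdict(entry.compound_id, outcomes, overall, reasons))
    return verdicts, counts


def survivors(verdicts: list[FilterVerdict]) -> set[str]:
    """Ids of compounds whose overall verdict is a pass."""
    return {v.compound_id for v in verdicts if v.overall}
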