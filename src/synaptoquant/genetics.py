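"""Mendelian progeny expectations for crosses with lethal classes and rescue.

Balancer chromosomes (TM6B, CyO) suppress recombination and are lethal when
homozygous, which makes expected progeny-class frequencies a small exercise in
conditional enumeration: list every equally likely gamete combination, remove
genotypes hit by a lethal rule (unless exempted by a rescue condition, e.g.
presence of a UAS rescue transgene), and renormalise over the survivors.

Crosses are described declaratively — per chromosome, the two alleles each
parent carries; lethal rules and progeny classes as predicates — and can be
loaded from YAML, so a cross ships as a data file.  Chromosomes assort
independently and no within-chromosome recombination is modelled (balancers
suppress it).

Predicate language (dicts, arbitrarily nested):

* ``{chromosome: C, genotype: [a, b]}`` — unordered allele pair on C,
* ``{chromosome: C, homozygous: a}`` — two copies of ``a`` on C,
* ``{carries: a}`` — at least one copy of ``a`` (optionally restricted with
  ``chromosome``),
* ``{all: [...]}, {any: [...]}, {not: ...}`` — boolean composition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .exceptions import DegenerateCrossError, ValidationError

__all__ = [
    "CrossSpec",
    "ProgenyDistribution",
    "expected_progeny",
    "observed_percentages",
    "load_cross",
    "load_table2_cross",
]

Genotype = dict  # chromosome -> sorted (allele, allele) tuple


def _eval_predicate(pred: Mapping, genotype: Genotype) -> bool:
    if not isinstance(pred, Mapping) or not pred:
        raise ValidationError(f"malformed predicate: {pred!r}")
    if "all" in pred:
        return all(_eval_predicate(p, genotype) for p in pred["all"])
    if "any" in pred:
        return any(_eval_predicate(p, genotype) for p in pred["any"])
    if "not" in pred:
        return not _eval_predicate(pred["not"], genotype)
    chrom = pred.get("chromosome")
    if "genotype" in pred:
        if chrom is None:
            raise ValidationError("'genotype' predicate requires 'chromosome'")
        want = tuple(sorted(str(a) for a in pred["genotype"]))
        return genotype[chrom] == want
    if "homozygous" in pred:
        if chrom is None:
            raise ValidationError("'homozygous' predicate requires 'chromosome'")
        a = str(pred["homozygous"])
        return genotype[chrom] == (a, a)
    if "carries" in pred:
        a = str(pred["carries"])
        pairs = [genotype[chrom]] if chrom is not None else genotype.values()
        return any(a in pair for pair in pairs)
    raise ValidationError(f"unrecognised predicate keys: {sorted(pred)}")


def _predicate_alleles(pred: Mapping) -> set[str]:
    out: set[str] = set()
    if "all" in pred or "any" in pred:
        for p in pred.get("all", pred.get("any")):
            out |= _predicate_alleles(p)
    elif "not" in pred:
        out |= _predicate_alleles(pred["not"])
    elif "genotype" in pred:
        out |= {str(a) for a in pred["genotype"]}
    elif "homozygous" in pred:
        out.add(str(pred["homozygous"]))
    elif "carries" in pred:
        out.add(str(pred["carries"]))
    return out


@dataclass
class LethalRule:
    predicate: Mapping
    unless: Mapping | None = None  # rescue exemption

    def kills(self, genotype: Genotype) -> bool:
        if not _eval_predicate(self.predicate, genotype):
            return False
        if self.unless is not None and _eval_predicate(self.unless, genotype):
            return False
        return True


@dataclass
class ProgenyClass:
    label: str
    where: Mapping


@dataclass
class CrossSpec:
    """Parental genotypes plus lethality/rescue rules and class definitions.

    ``chromosomes`` maps a chromosome name to ``(maternal_pair,
    paternal_pair)``; each parent contributes exactly one allele of its pair
    per gamete, with equal segregation.
    """

    chromosomes: dict[str, tuple[tuple[str, str], tuple[str, str]]]
    lethal_rules: list[LethalRule] = field(default_factory=list)
    classes: list[ProgenyClass] = field(default_factory=list)
    name: str = "cross"

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValidationError("a cross needs at least one chromosome")
        declared: set[str] = set()
        for chrom, (mat, pat) in self.chromosomes.items():
            if len(mat) != 2 or len(pat) != 2:
                raise ValidationError(
                    f"chromosome {chrom!r}: each parent must carry exactly two alleles"
                )
            declared |= set(map(str, mat)) | set(map(str, pat))
        referenced: set[str] = set()
        for rule in self.lethal_rules:
            referenced |= _predicate_alleles(rule.predicate)
            if rule.unless is not None:
                referenced |= _predicate_alleles(rule.unless)
        for cls in self.classes:
            referenced |= _predicate_alleles(cls.where)
        unknown = referenced - declared
        if unknown:
            raise ValidationError(f"rules reference undeclared alleles: {sorted(unknown)}")

    @classmethod
    def from_dict(cls, spec: Mapping) -> "CrossSpec":
        chroms = {}
        for chrom, parents in spec["chromosomes"].items():
            chroms[str(chrom)] = (
                tuple(str(a) for a in parents["mother"]),
                tuple(str(a) for a in parents["father"]),
            )
        rules = [
            LethalRule(predicate=r["predicate"], unless=r.get("unless"))
            for r in spec.get("lethal", [])
        ]
        classes = [ProgenyClass(label=c["label"], where=c["where"]) for c in spec.get("classes", [])]
        return cls(
            chromosomes=chroms,
            lethal_rules=rules,
            classes=classes,
            name=spec.get("name", "cross"),
        )

    @classmethod
    def from_yaml(cls, source) -> "CrossSpec":
        if hasattr(source, "read"):
            return cls.from_dict(yaml.safe_load(source))
        with open(source, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class ProgenyDistribution:
    """Expected percentages of each progeny class among viable adults."""

    percentages: dict[str, float]
    viable_mass: float  # fraction of conceptions surviving
    conception: dict[str, float]  # class frequency before lethality
    surviving: dict[str, float]  # class frequency after lethality, pre-normalisation
    n_genotypes: int  # gamete combinations enumerated

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "expected_pct": self.percentages,
                "conception_fraction": self.conception,
                "surviving_fraction": self.surviving,
            }
        ).rename_axis("class")


def _classify(genotype: Genotype, classes: Sequence[ProgenyClass]) -> str:
    if not classes:
        # no declared classes: label by the full genotype
        return "; ".join(f"{c}:{a}/{b}" for c, (a, b) in sorted(genotype.items()))
    for cls in classes:
        if _eval_predicate(cls.where, genotype):
            return cls.label
    return "other"


def expected_progeny(cross: CrossSpec) -> ProgenyDistribution:
    """Enumerate gamete combinations, apply lethality, renormalise survivors.

    Each parent segregates its two alleles 1:1 per chromosome and chromosomes
    assort independently, so every maternal/paternal allele combination is
    equally likely.  Classes whose every genotype is lethal report 0%.
    """
    chrom_names = list(cross.chromosomes)
    genotypes: list[Genotype] = [{}]
    for chrom in chrom_names:
        mat, pat = cross.chromosomes[chrom]
        expanded = []
        for g in genotypes:
            for m in mat:
                for f in pat:
                    g2 = dict(g)
                    g2[chrom] = tuple(sorted((str(m), str(f))))
                    expanded.append(g2)
        genotypes = expanded
    mass = 1.0 / len(genotypes)

    labels = [c.label for c in cross.classes] or None
    conception: dict[str, float] = {}
    surviving: dict[str, float] = {}
    viable = 0.0
    for g in genotypes:
        label = _classify(g, cross.classes)
        conception[label] = conception.get(label, 0.0) + mass
        if any(rule.kills(g) for rule in cross.lethal_rules):
            continue
        surviving[label] = surviving.get(label, 0.0) + mass
        viable += mass
    if viable == 0:
        raise DegenerateCrossError(f"cross {cross.name!r}: every progeny class is lethal")

    all_labels = labels if labels is not None else sorted(conception)
    if "other" in conception and labels is not None:
        all_labels = all_labels + ["other"]
    percentages = {lb: 100.0 * surviving.get(lb, 0.0) / viable for lb in all_labels}
    return ProgenyDistribution(
        percentages=percentages,
        viable_mass=viable,
        conception={lb: conception.get(lb, 0.0) for lb in all_labels},
        surviving={lb: surviving.get(lb, 0.0) for lb in all_labels},
        n_genotypes=len(genotypes),
    )


def observed_percentages(
    class_counts: Mapping[str, int], total: int
) -> pd.DataFrame:
    """Observed class percentages: 100 * count / total.

    Returns both the raw percentage and the value rounded to one decimal (the
    reporting convention); comparisons should use the raw column.
    """
    if total <= 0:
        raise ValidationError("total must be > 0")
    counts = {k: int(v) for k, v in class_counts.items()}
    if any(v < 0 for v in counts.values()):
        raise ValidationError("counts must be >= 0")
    if sum(counts.values()) > total:
        raise ValidationError("counts sum exceeds the total")
    rows = {
        k: {"count": v, "raw_pct": 100.0 * v / total, "pct": round(100.0 * v / total, 1)}
        for k, v in counts.items()
    }
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("class")


def load_cross(path) -> CrossSpec:
    """Load a cross description from a YAML file."""
    return CrossSpec.from_yaml(path)


def load_table2_cross() -> CrossSpec:
    """The bundled rescue cross: driver-bearing mutant/balancer females to
    effector/balancer deficiency males, with balancer-homozygote lethality and
    transgene-conditional rescue of the mutant-over-deficiency class."""
    ref = resources.files("synaptoquant.data").joinpath("table2_cross.yaml")
    with ref.open("r", encoding="utf-8") as fh:
        return CrossSpec.from_yaml(fh)
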