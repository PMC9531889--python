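"""Parcellation region registry.

The registry is the single source of truth for region labels: which
anatomical category a region belongs to, which metrics are measured on it
(cortical regions carry both thickness and volume, everything else volume
only), whether it is reported per hemisphere or once per subject, and which
denominator its volume is normalized by (intracranial volume, whole
hippocampus, or whole amygdala).

Labels are canonicalized case-insensitively with spaces, hyphens and
underscores interchangeable, so ``"CA-1 head"``, ``"ca1_head"`` and
``"CA1-head"`` (the FreeSurfer subfield-file spelling) all resolve to the
same descriptor.  A small alias table covers FreeSurfer spellings that do
not collapse onto a registry label by canonicalization alone.
"""

from __future__ import annotations

import difflib
import re
from dataclasses import dataclass
from pathlib import Path

from .errors import ParseError, UnknownRegionError, ValidationError

CORTICAL = "cortical"
SUBCORTICAL = "subcortical"
HIPPOCAMPAL_SUBFIELD = "hippocampal_subfield"
AMYGDALAR_NUCLEUS = "amygdalar_nucleus"
CATEGORIES = (CORTICAL, SUBCORTICAL, HIPPOCAMPAL_SUBFIELD, AMYGDALAR_NUCLEUS)

THICKNESS = "thickness"
VOLUME = "volume"
METRICS = (THICKNESS, VOLUME)

NORM_ICV = "ICV"
NORM_WHOLE_HIPPOCAMPUS = "whole_hippocampus"
NORM_WHOLE_AMYGDALA = "whole_amygdala"
NORM_NONE = "none"
NORM_PARENTS = (NORM_ICV, NORM_WHOLE_HIPPOCAMPUS, NORM_WHOLE_AMYGDALA, NORM_NONE)

WHOLE_HIPPOCAMPUS = "Whole hippocampus"
WHOLE_AMYGDALA = "Whole amygdala"

_CANON_RE = re.compile(r"[^a-z0-9]+")


def canonicalize(name: str) -> str:
    """Collapse a region label to its canonical comparison token."""
    return _CANON_RE.sub("", name.lower())


@dataclass(frozen=True)
class RegionDescriptor:
    """One named parcellation unit."""

    name: str
    category: str
    metrics: frozenset[str]
    hemispheric: bool
    norm_parent: str
    aliases: tuple[str, ...] = ()

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValidationError(f"bad category {self.category!r} for {self.name!r}")
        if not self.metrics or not self.metrics <= set(METRICS):
            raise ValidationError(f"bad metrics {set(self.metrics)!r} for {self.name!r}")
        if self.norm_parent not in NORM_PARENTS:
            raise ValidationError(f"bad norm_parent {self.norm_parent!r} for {self.name!r}")
        if self.category == CORTICAL and THICKNESS not in self.metrics:
            raise ValidationError(f"cortical region {self.name!r} must carry thickness")
        if self.category != CORTICAL and self.metrics != {VOLUME}:
            raise ValidationError(f"non-cortical region {self.name!r} must be volume-only")


class RegionRegistry:
    """Immutable collection of :class:`RegionDescriptor` keyed by canonical label."""

    def __init__(self, descriptors: list[RegionDescriptor]):
        self.descriptors: tuple[RegionDescriptor, ...] = tuple(descriptors)
        self._by_canonical: dict[str, RegionDescriptor] = {}
        for desc in self.descriptors:
            for label in (desc.name, *desc.aliases):
                key = canonicalize(label)
                prior = self._by_canonical.get(key)
                if prior is not None and prior is not desc:
                    raise ValidationError(
                        f"label {label!r} maps onto both {prior.name!r} and {desc.name!r}"
                    )
                self._by_canonical[key] = desc
        names = [d.name for d in self.descriptors]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate region names in registry")

    def __len__(self) -> int:
        return len(self.descriptors)

    def __iter__(self):
        return iter(self.descriptors)

    def __eq__(self, other) -> bool:
        return isinstance(other, RegionRegistry) and self.descriptors == other.descriptors

    def __contains__(self, name: str) -> bool:
        return canonicalize(name) in self._by_canonical

    def lookup(self, name: str) -> RegionDescriptor:
        """Resolve a label (any spelling) to its descriptor.

        Raises :class:`UnknownRegionError` naming the nearest candidate
        labels when the name does not resolve.
        """
        desc = self._by_canonical.get(canonicalize(name))
        if desc is None:
            near = difflib.get_close_matches(
                canonicalize(name), list(self._by_canonical), n=3, cutoff=0.6
            )
            candidates = sorted({self._by_canonical[k].name for k in near})
            raise UnknownRegionError(name, candidates)
        return desc

    def names(self) -> list[str]:
        return [d.name for d in self.descriptors]

    def category_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in CATEGORIES}
        for d in self.descriptors:
            counts[d.category] += 1
        return counts

    # -- flat-file round trip ------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("name\tcategory\tmetrics\themispheric\tnorm_parent\taliases\n")
            for d in self.descriptors:
                fh.write(
                    "\t".join(
                        [
                            d.name,
                            d.category,
                            ",".join(sorted(d.metrics)),
                            str(d.hemispheric).lower(),
                            d.norm_parent,
                            "|".join(d.aliases),
                        ]
                    )
                    + "\n"
                )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RegionRegistry":
        descriptors = []
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n").split("\t")
            expected = ["name", "category", "metrics", "hemispheric", "norm_parent", "aliases"]
            if header != expected:
                raise ParseError(f"bad registry header {header!r}", str(path), 1)
            for lineno, line in enumerate(fh, start=2):
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) != 6:
                    raise ParseError(f"expected 6 columns, got {len(parts)}", str(path), lineno)
                name, category, metrics, hemispheric, norm_parent, aliases = parts
                if hemispheric not in ("true", "false"):
                    raise ParseError(f"bad hemispheric flag {hemispheric!r}", str(path), lineno)
                descriptors.append(
                    RegionDescriptor(
                        name=name,
                        category=category,
                        metrics=frozenset(metrics.split(",")),
                        hemispheric=hemispheric == "true",
                        norm_parent=norm_parent,
                        aliases=tuple(a for a in aliases.split("|") if a),
                    )
                )
        return cls(descriptors)


# ---------------------------------------------------------------------------
# Default inventory: 34 cortical + 23 subcortical + 22 hippocampal subfields
# + 10 amygdalar nuclei = 89 regions.
# ---------------------------------------------------------------------------

_CORTICAL = [
    "Bankssts",
    "Caudal anterior cingulate",
    "Caudal middle frontal",
    "Cuneus",
    "Entorhinal",
    "Fusiform",
    "Inferior parietal",
    "Inferior temporal",
    "Isthmus cingulate",
    "Lateral occipital",
    "Lateral orbitofrontal",
    "Lingual",
    "Medial orbitofrontal",
    "Middle temporal",
    "Parahippocampal",
    "Paracentral",
    "Pars opercularis",
    "Pars orbitalis",
    "Pars triangularis",
    "Pericalcarine",
    "Post-central",
    "Posterior cingulate",
    "Pre-central",
    "Pre-cuneus",
    "Rostral anterior cingulate",
    "Rostral middle frontal",
    "Superior frontal",
    "Superior parietal",
    "Superior temporal",
    "Supramarginal",
    "Frontal pole",
    "Temporal pole",
    "Transverse temporal",
    "Insula",
]

# (name, hemispheric, aliases)
_SUBCORTICAL = [
    ("Lateral-ventricle", True, ()),
    ("Inf-Lat-Vent", True, ("Inferior lateral ventricle",)),
    ("Cerebellum white matter", True, ("Cerebellum-White-Matter",)),
    ("Cerebellum cortex", True, ("Cerebellum-Cortex",)),
    ("Caudate", True, ()),
    ("Putamen", True, ()),
    ("Pallidum", True, ()),
    ("Hippocampus", True, ()),
    ("Amygdala", True, ()),
    ("Accumbens area", True, ("Accumbens-area",)),
    ("Cortex", True, ("CortexVol",)),
    ("Cerebral white matter", True, ("CerebralWhiteMatterVol",)),
    ("Corpus callosum posterior", False, ("CC_Posterior",)),
    ("Corpus callosum midposterior", False, ("CC_Mid_Posterior",)),
    ("Corpus callosum central", False, ("CC_Central",)),
    ("Corpus callosum midanterior", False, ("CC_Mid_Anterior",)),
    ("Corpus callosum anterior", False, ("CC_Anterior",)),
    ("Third ventricle", False, ("3rd-Ventricle",)),
    ("Fourth ventricle", False, ("4th-Ventricle",)),
    ("CSF", False, ()),
    ("Brainstem", False, ("Brain-Stem", "BrainStemVol")),
    ("Brain Seg Vol", False, ("BrainSegVol",)),
    ("Total Gray Vol", False, ("TotalGrayVol",)),
]

_HIPPOCAMPAL_SUBFIELDS = [
    ("Hippocampal tail", ("Hippocampal_tail",)),
    ("Subiculum body", ("subiculum-body",)),
    ("CA-1 body", ("CA1-body",)),
    ("Subiculum head", ("subiculum-head",)),
    ("Hippocampal fissure", ("hippocampal-fissure",)),
    ("Presubiculum head", ("presubiculum-head",)),
    ("CA-1 head", ("CA1-head",)),
    ("Pre-subiculum body", ("presubiculum-body",)),
    ("Parasubiculum", ()),
    ("Molecular layer HP head", ("molecular_layer_HP-head",)),
    ("Molecular layer HP body", ("molecular_layer_HP-body",)),
    ("GC-ML-DG-head", ()),
    ("CA-3 body", ("CA3-body",)),
    ("GC-ML-DG body", ("GC-ML-DG-body",)),
    ("CA-4 head", ("CA4-head",)),
    ("CA-4 body", ("CA4-body",)),
    ("Fimbria", ()),
    ("CA-3 head", ("CA3-head",)),
    ("HATA", ()),
    ("Whole hippocampal body", ("Whole_hippocampal_body",)),
    ("Whole hippocampal head", ("Whole_hippocampal_head",)),
    (WHOLE_HIPPOCAMPUS, ("Whole_hippocampus",)),
]

_AMYGDALAR_NUCLEI = [
    ("Lateral nucleus", ("Lateral-nucleus",)),
    ("Basal nucleus", ("Basal-nucleus",)),
    ("Accessory basal nucleus", ("Accessory-Basal-nucleus",)),
    ("Anterior amygdaloid area", ("Anterior-amygdaloid-area-AAA",)),
    ("Central nucleus", ("Central-nucleus",)),
    ("Medial nucleus", ("Medial-nucleus",)),
    ("Cortical nucleus", ("Cortical-nucleus",)),
    ("Cortical amygdaloid transition", ("Corticoamygdaloid-transitio",)),
    ("Paralaminar nucleus", ("Paralaminar-nucleus",)),
    (WHOLE_AMYGDALA, ("Whole_amygdala",)),
]


def build_default_registry() -> RegionRegistry:
    """Assemble the default 89-region inventory.

    Deterministic and side-effect free: two calls compare equal.
    """
    descriptors: list[RegionDescriptor] = []
    for name in _CORTICAL:
        descriptors.append(
            RegionDescriptor(
                name=name,
                category=CORTICAL,
                metrics=frozenset({THICKNESS, VOLUME}),
                hemispheric=True,
                norm_parent=NORM_ICV,
            )
        )
    for name, hemispheric, aliases in _SUBCORTICAL:
        descriptors.append(
            RegionDescriptor(
                name=name,
                category=SUBCORTICAL,
                metrics=frozenset({VOLUME}),
                hemispheric=hemispheric,
                norm_parent=NORM_ICV,
                aliases=aliases,
            )
        )
    for name, aliases in _HIPPOCAMPAL_SUBFIELDS:
        descriptors.append(
            RegionDescriptor(
                name=name,
                category=HIPPOCAMPAL_SUBFIELD,
                metrics=frozenset({VOLUME}),
                hemispheric=True,
                norm_parent=NORM_ICV if name == WHOLE_HIPPOCAMPUS else NORM_WHOLE_HIPPOCAMPUS,
                aliases=aliases,
            )
        )
    for name, aliases in _AMYGDALAR_NUCLEI:
        descriptors.append(
            RegionDescriptor(
                name=name,
                category=AMYGDALAR_NUCLEUS,
                metrics=frozenset({VOLUME}),
                hemispheric=True,
                norm_parent=NORM_ICV if name == WHOLE_AMYGDALA else NORM_WHOLE_AMYGDALA,
                aliases=aliases,
            )
        )
    return RegionRegistry(descriptors)
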