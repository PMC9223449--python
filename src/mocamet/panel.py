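"""Targeted-panel taxonomy for Biocrates p180-style metabolite names.

The analytes of a p180-like targeted kit fall into seven classes:
acylcarnitines, amino acids, biogenic amines, phosphatidylcholines (PC),
lysophosphatidylcholines (lysoPC), sphingomyelins (SM) and the hexose sum.
Lipid-like analytes and acylcarnitines carry a ``C X:Y`` suffix encoding the
acyl chain: X carbons, Y double bonds.  That suffix drives every class sum and
ratio downstream (long-chain acylcarnitines, saturated vs. unsaturated
lysoPC, ...), so it is parsed into explicit descriptor fields here.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional


class MetaboliteClass(str, Enum):
    ACYLCARNITINE = "acylcarnitine"
    AMINOACID = "aminoacid"
    BIOGENIC_AMINE = "biogenic_amine"
    PHOSPHATIDYLCHOLINE = "phosphatidylcholine"
    LYSOPHOSPHATIDYLCHOLINE = "lysophosphatidylcholine"
    SPHINGOMYELIN = "sphingomyelin"
    HEXOSE = "hexose"


#: Classes whose names carry an acyl-chain "C X:Y" code.
ACYL_CLASSES = frozenset(
    {
        MetaboliteClass.ACYLCARNITINE,
        MetaboliteClass.PHOSPHATIDYLCHOLINE,
        MetaboliteClass.LYSOPHOSPHATIDYLCHOLINE,
        MetaboliteClass.SPHINGOMYELIN,
    }
)

# p180 amino-acid panel (21 analytes).
AMINO_ACIDS = (
    "Ala", "Arg", "Asn", "Asp", "Cit", "Gln", "Glu", "Gly", "His", "Ile",
    "Leu", "Lys", "Met", "Orn", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr",
    "Val",
)

# p180 biogenic-amine panel (21 analytes).  Taurine and the arginine
# derivatives (ADMA, SDMA, total DMA) live here, not with the amino acids.
BIOGENIC_AMINES = (
    "Ac-Orn", "ADMA", "alpha-AAA", "Carnosine", "Creatinine", "DOPA",
    "Dopamine", "Histamine", "Kynurenine", "Met-SO", "Nitro-Tyr",
    "PEA", "Putrescine", "Sarcosine", "SDMA", "Serotonin", "Spermidine",
    "Spermine", "t4-OH-Pro", "Taurine", "total DMA",
)

_ACYL_RE = re.compile(r"C\s?(\d+)(?::(\d+))?")


@dataclass(frozen=True)
class MetaboliteDescriptor:
    """One panel analyte with its class and (optional) acyl-chain geometry."""

    name: str
    metabolite_class: MetaboliteClass
    acyl_carbons: Optional[int] = None
    acyl_double_bonds: Optional[int] = None

    def __post_init__(self) -> None:
        has_acyl = self.acyl_carbons is not None
        if has_acyl != (self.metabolite_class in ACYL_CLASSES):
            raise ValueError(
                f"{self.name!r}: acyl fields must be present exactly for "
                f"lipid-like/acylcarnitine classes, got class "
                f"{self.metabolite_class.value} with acyl_carbons="
                f"{self.acyl_carbons}"
            )
        if has_acyl:
            if self.acyl_carbons < 0 or (self.acyl_double_bonds or 0) < 0:
                raise ValueError(f"{self.name!r}: negative acyl geometry")

    @property
    def is_saturated(self) -> Optional[bool]:
        """True when the acyl moiety has no double bond; None for non-lipids."""
        if self.acyl_double_bonds is None:
            return None
        return self.acyl_double_bonds == 0


def parse_metabolite_name(name: str) -> MetaboliteDescriptor:
    """Classify a panel analyte from its export header name.

    The grammar follows Biocrates conventions: ``PC aa C36:2`` /
    ``PC ae C38:0`` (phosphatidylcholines), ``lysoPC a C18:1``,
    ``SM C16:0`` / ``SM (OH) C14:1``, acylcarnitines ``C0``, ``C5-OH``,
    ``C18:1``, hexoses ``H1``, and the fixed amino-acid / biogenic-amine name
    lists.  Raises ``ValueError`` for names outside the grammar.
    """
    name = name.strip()
    if not name:
        raise ValueError("empty metabolite name")
    if name in AMINO_ACIDS:
        return MetaboliteDescriptor(name, MetaboliteClass.AMINOACID)
    if name in BIOGENIC_AMINES:
        return MetaboliteDescriptor(name, MetaboliteClass.BIOGENIC_AMINE)
    if re.fullmatch(r"H\d+", name):
        return MetaboliteDescriptor(name, MetaboliteClass.HEXOSE)
    if name.startswith("PC "):
        cls = MetaboliteClass.PHOSPHATIDYLCHOLINE
    elif name.lower().startswith("lysopc"):
        cls = MetaboliteClass.LYSOPHOSPHATIDYLCHOLINE
    elif name.startswith("SM"):
        cls = MetaboliteClass.SPHINGOMYELIN
    elif re.fullmatch(r"C\d+.*", name):
        cls = MetaboliteClass.ACYLCARNITINE
    else:
        raise ValueError(f"unrecognized metabolite name: {name!r}")
    # acylcarnitine suffixes (-OH, -DC) modify the chain but keep the C X:Y core
    m = (_ACYL_RE.match(name) if cls is MetaboliteClass.ACYLCARNITINE
         else _ACYL_RE.search(name))
    if m is None:
        raise ValueError(f"{name!r}: no acyl 'C X:Y' code found")
    carbons = int(m.group(1))
    double_bonds = int(m.group(2)) if m.group(2) else 0
    return MetaboliteDescriptor(name, cls, carbons, double_bonds)


def build_panel(names: Iterable[str]) -> list[MetaboliteDescriptor]:
    """Parse a sequence of header names into descriptors, enforcing uniqueness."""
    descriptors = []
    seen: set[str] = set()
    for raw in names:
        d = parse_metabolite_name(raw)
        if d.name in seen:
            raise ValueError(f"duplicate metabolite name: {d.name!r}")
        seen.add(d.name)
        descriptors.append(d)
    return descriptors


def _default_pc_names() -> list[str]:
    # 38 diacyl (aa) + 38 acyl-alkyl (ae) species, p180-style C X:Y grid
    aa = [
        "C24:0", "C26:0", "C28:1", "C30:0", "C32:0", "C32:1", "C32:2",
        "C32:3", "C34:1", "C34:2", "C34:3", "C34:4", "C36:0", "C36:1",
        "C36:2", "C36:3", "C36:4", "C36:5", "C36:6", "C38:0", "C38:3",
        "C38:4", "C38:5", "C38:6", "C40:1", "C40:2", "C40:3", "C40:4",
        "C40:5", "C40:6", "C42:0", "C42:1", "C42:2", "C42:4", "C42:5",
        "C42:6", "C30:2", "C44:3",
    ]
    ae = [
        "C30:0", "C30:1", "C30:2", "C32:1", "C32:2", "C34:0", "C34:1",
        "C34:2", "C34:3", "C36:0", "C36:1", "C36:2", "C36:3", "C36:4",
        "C36:5", "C38:0", "C38:1", "C38:2", "C38:3", "C38:4", "C38:5",
        "C38:6", "C40:1", "C40:2", "C40:3", "C40:4", "C40:5", "C40:6",
        "C42:0", "C42:1", "C42:2", "C42:3", "C42:4", "C42:5", "C44:4",
        "C44:5", "C44:6", "C46:0",
    ]
    return [f"PC aa {s}" for s in aa] + [f"PC ae {s}" for s in ae]


def default_panel() -> list[MetaboliteDescriptor]:
    """The default 188-analyte p180-like panel.

    40 acylcarnitines, 21 amino acids, 21 biogenic amines, 76 PC,
    14 lysoPC, 15 SM and one hexose sum.
    """
    acylcarnitines = [
        "C0", "C2", "C3", "C3:1", "C3-OH", "C4", "C4:1", "C4-OH", "C5",
        "C5:1", "C5:1-DC", "C5-DC", "C5-M-DC", "C5-OH", "C6", "C6:1",
        "C7-DC", "C8", "C9", "C10", "C10:1", "C10:2", "C12", "C12:1",
        "C12-DC", "C14", "C14:1", "C14:1-OH", "C14:2", "C14:2-OH", "C16",
        "C16:1", "C16:1-OH", "C16:2", "C16:2-OH", "C16-OH", "C18", "C18:1",
        "C18:1-OH", "C18:2",
    ]
    lysopc = [
        "lysoPC a C14:0", "lysoPC a C16:0", "lysoPC a C16:1",
        "lysoPC a C17:0", "lysoPC a C18:0", "lysoPC a C18:1",
        "lysoPC a C18:2", "lysoPC a C20:3", "lysoPC a C20:4",
        "lysoPC a C24:0", "lysoPC a C26:0", "lysoPC a C26:1",
        "lysoPC a C28:0", "lysoPC a C28:1",
    ]
    sm = [
        "SM C16:0", "SM C16:1", "SM C18:0", "SM C18:1", "SM C20:2",
        "SM C24:0", "SM C24:1", "SM C26:0", "SM C26:1", "SM (OH) C14:1",
        "SM (OH) C16:1", "SM (OH) C22:1", "SM (OH) C22:2", "SM (OH) C24:1",
        "SM C22:3",
    ]
    names = (
        acylcarnitines
        + list(AMINO_ACIDS)
        + list(BIOGENIC_AMINES)
        + _default_pc_names()
        + lysopc
        + sm
        + ["H1"]
    )
    panel = build_panel(names)
    assert len(panel) == 188
    return panel
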