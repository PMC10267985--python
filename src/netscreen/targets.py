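"""Named gene-symbol sets with provenance and per-gene support."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path


@dataclass
class TargetSet:
    """A deduplicated set of gene symbols with provenance.

    ``support`` maps each gene to the distinct sources that nominated it
    (ingredient names for drug targets, study ids for disease targets),
    so overlap statistics survive the pooling step.
    """

    name: str
    genes: set[str]
    provenance: str = "drug"  # "drug" | "disease"
    support: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.genes = {g.upper() for g in self.genes}

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes

    def multi_supported(self, k: int = 2) -> set[str]:
        """Genes nominated by at least *k* distinct sources."""
        return {g for g, src in self.support.items() if len(set(src)) >= k}

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("gene\tn_sources\tsources\n")
            for g in sorted(self.genes):
                src = sorted(set(self.support.get(g, [])))
                fh.write(f"{g}\t{len(src)}\t{','.join(src)}\n")

    @classmethod
    def from_tsv(cls, path: str | Path, name: str | None = None, provenance: str = "drug") -> "TargetSet":
        genes: set[str] = set()
        support: dict[str, list[str]] = {}
        with open(path) as fh:
            header = fh.readline()
            has_header = header.strip().lower().startswith("gene")
            if not has_header and header.strip():
                parts = header.rstrip("\n").split("\t")
                genes.add(parts[0].upper())
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if not parts[0]:
                    continue
                g = parts[0].upper()
                genes.add(g)
                if len(parts) >= 3 and parts[2]:
                    support[g] = parts[2].split(",")
        return cls(name=name or Path(path).stem, genes=genes, provenance=provenance, support=support)
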