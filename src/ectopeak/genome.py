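"""Genome description: ordered chromosome lengths plus the centromere mask."""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .intervals import PeakSet

# The centromere mask is just a PeakSet of boundary intervals.
CentromereMask = PeakSet


@dataclass
class GenomeSpec:
    """Chromosome lengths (ordered) and per-chromosome centromere intervals.

    For real data the mask comes from a centromere-boundary BED (e.g. the
    UCSC annotation for the assembly the reads were aligned to); for
    synthetic genomes it is generated.
    """

    chrom_lengths: dict[str, int]
    centromeres: CentromereMask = field(default_factory=PeakSet.empty)

    def __post_init__(self) -> None:
        if not self.chrom_lengths:
            raise ValueError("genome must have at least one chromosome")
        for chrom, length in self.chrom_lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom} has nonpositive length {length}")
        for iv in self.centromeres:
            if iv.chrom not in self.chrom_lengths:
                raise ValueError(f"centromere on unknown chromosome {iv.chrom}")
            if iv.end > self.chrom_lengths[iv.chrom]:
                raise ValueError(
                    f"centromere {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome end"
                )

    @property
    def chroms(self) -> list[str]:
        return list(self.chrom_lengths)

    @property
    def total_length(self) -> int:
        return sum(self.chrom_lengths.values())

    def to_dict(self) -> dict:
        return {
            "chroms": dict(self.chrom_lengths),
            "centromeres": [[iv.chrom, iv.start, iv.end] for iv in self.centromeres],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GenomeSpec":
        mask = PeakSet.from_intervals(
            [(c, int(s), int(e)) for c, s, e in d.get("centromeres", [])],
            label="centromeres",
        )
        return cls(chrom_lengths={c: int(v) for c, v in d["chroms"].items()},
                   centromeres=mask)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GenomeSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
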