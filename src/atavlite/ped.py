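"""PLINK-style PED sample files: family structure and affectedness."""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

from .errors import ParseError, ValidationError

MISSING_PARENT = "0"


@dataclass(frozen=True)
class SampleRecord:
    """One row of a PLINK PED sample table.

    sex: 1=male, 2=female, 0=unknown.
    phenotype: 2=affected (case), 1=unaffected (control), 0 or -9 = missing.
    """

    family_id: str
    sample_id: str
    paternal_id: str = MISSING_PARENT
    maternal_id: str = MISSING_PARENT
    sex: int = 0
    phenotype: int = 0

    def __post_init__(self):
        if self.sex not in (0, 1, 2):
            raise ValidationError(f"sex must be 0/1/2, got {self.sex}")
        if self.phenotype not in (2, 1, 0, -9):
            raise ValidationError(f"phenotype must be 2/1/0/-9, got {self.phenotype}")

    @property
    def is_case(self) -> bool:
        return self.phenotype == 2

    @property
    def is_control(self) -> bool:
        return self.phenotype == 1

    @property
    def is_founder(self) -> bool:
        return self.paternal_id == MISSING_PARENT and self.maternal_id == MISSING_PARENT


def read_ped(path) -> List[SampleRecord]:
    """Parse a 6-column whitespace-delimited PED sample file."""
    records = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise ParseError(f"{path}:{ln}: PED rows need 6 columns, got {len(fields)}")
            try:
                records.append(
                    SampleRecord(
                        family_id=fields[0],
                        sample_id=fields[1],
                        paternal_id=fields[2],
                        maternal_id=fields[3],
                        sex=int(fields[4]),
                        phenotype=int(fields[5]),
                    )
                )
            except (ValueError, ValidationError) as exc:
                raise ParseError(f"{path}:{ln}: {exc}") from None
    seen = set()
    for r in records:
        if r.sample_id in seen:
            raise ParseError(f"duplicate sample id {r.sample_id!r} in {path}")
        seen.add(r.sample_id)
    return records


def write_ped(records: Sequence[SampleRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                f"{r.family_id}\t{r.sample_id}\t{r.paternal_id}\t{r.maternal_id}"
                f"\t{r.sex}\t{r.phenotype}\n"
            )


def cases(records: Sequence[SampleRecord]) -> List[SampleRecord]:
    return [r for r in records if r.is_case]


def controls(records: Sequence[SampleRecord]) -> List[SampleRecord]:
    return [r for r in records if r.is_control]
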