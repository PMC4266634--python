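"""Pedigree representation and PED-format I/O.

A pedigree assigns each sample to a family, links children to their
parents, and records affected status.  The inheritance filter uses it to
decide which genotype columns must show the homozygous-in-probands /
heterozygous-in-parents pattern.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

PED_COLUMNS = ["family", "sample", "father", "mother", "sex", "phenotype"]

# PED phenotype codes
_UNAFFECTED = 1
_AFFECTED = 2


@dataclass(frozen=True)
class Sample:
    sample_id: str
    family_id: str
    father_id: str | None
    mother_id: str | None
    sex: int  # 1 male, 2 female, 0 unknown
    affected: bool


class PedigreeError(ValueError):
    pass


class Pedigree:
    """Samples grouped by family with parent links and affected status."""

    def __init__(self, samples: list[Sample]):
        self._samples: dict[str, Sample] = {}
        for s in samples:
            if s.sample_id in self._samples:
                raise PedigreeError(f"duplicate sample id {s.sample_id!r}")
            self._samples[s.sample_id] = s
        self._validate_links()

    def _validate_links(self) -> None:
        for s in self._samples.values():
            for pid in (s.father_id, s.mother_id):
                if pid is None:
                    continue
                parent = self._samples.get(pid)
                if parent is None:
                    raise PedigreeError(
                        f"sample {s.sample_id!r} references missing parent {pid!r}"
                    )
                if parent.family_id != s.family_id:
                    raise PedigreeError(
                        f"parent {pid!r} of {s.sample_id!r} is in a different family"
                    )

    def __len__(self) -> int:
        return len(self._samples)

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self._samples

    def __getitem__(self, sample_id: str) -> Sample:
        return self._samples[sample_id]

    @property
    def sample_ids(self) -> list[str]:
        return list(self._samples)

    @property
    def samples(self) -> list[Sample]:
        return list(self._samples.values())

    def affected(self) -> list[Sample]:
        return [s for s in self._samples.values() if s.affected]

    def parents_of(self, sample_id: str) -> list[Sample]:
        s = self._samples[sample_id]
        out = []
        for pid in (s.father_id, s.mother_id):
            if pid is not None:
                out.append(self._samples[pid])
        return out

    def families(self) -> dict[str, list[Sample]]:
        fams: dict[str, list[Sample]] = {}
        for s in self._samples.values():
            fams.setdefault(s.family_id, []).append(s)
        return fams

    def required_samples(self) -> list[str]:
        """Affected children plus every parent of an affected child.

        These are the samples whose genotypes the inheritance filter
        inspects; all other samples are ignored by that filter.
        """
        seen: dict[str, None] = {}
        for child in self.affected():
            seen.setdefault(child.sample_id)
            for p in self.parents_of(child.sample_id):
                seen.setdefault(p.sample_id)
        return list(seen)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (
                s.family_id,
                s.sample_id,
                s.father_id or "0",
                s.mother_id or "0",
                s.sex,
                _AFFECTED if s.affected else _UNAFFECTED,
            )
            for s in self._samples.values()
        ]
        return pd.DataFrame(rows, columns=PED_COLUMNS)


def read_ped(path) -> Pedigree:
    """Read a 6-column PED file (family, id, father, mother, sex, phenotype)."""
    df = pd.read_csv(path, sep=r"\s+", header=None, names=PED_COLUMNS, dtype=str)
    samples = []
    for row in df.itertuples(index=False):
        samples.append(
            Sample(
                sample_id=row.sample,
                family_id=row.family,
                father_id=None if row.father in ("0", ".") else row.father,
                mother_id=None if row.mother in ("0", ".") else row.mother,
                sex=int(row.sex),
                affected=int(row.phenotype) == _AFFECTED,
            )
        )
    return Pedigree(samples)


def write_ped(pedigree: Pedigree, path) -> None:
    pedigree.to_frame().to_csv(path, sep="\t", header=False, index=False)
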