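"""Reading and writing of STR typing data.

Handles GeneMapper-style genotype-table exports (tab-delimited text with
allele designations, peak heights in RFU and fragment sizes in bp), allele
frequency tables, and kit size maps; applies the analytical threshold (AT)
below which peaks are not called.

Two reserved allele symbols are used internally and never appear on disk:

``LOSS``
    an allele copy lost from a tumor genotype (loss of heterozygosity),
``Q``
    the aggregate of all alleles not explicitly enumerated at a locus,
    carrying the residual population frequency mass.
"""

from __future__ import annotations

import json
import logging
import math
import re
from dataclasses import dataclass, field

import pandas as pd
import yaml

logger = logging.getLogger("tumorlr")

#: reserved designation: a lost allele copy (no physical fragment)
LOSS = "LOSS"
#: reserved designation: aggregate unobserved allele
Q = "Q"

DEFAULT_AT = 175.0  # RFU


class FormatError(ValueError):
    """A file does not conform to the expected layout."""


class ValidationError(ValueError):
    """Input data violates a model constraint."""


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Peak:
    """One called peak: allele designation, height (RFU) and size (bp).

    Reference profiles carry no height information; ``height`` is None there.
    """

    allele: str
    height: float | None
    size: float | None

    def __post_init__(self):
        if not self.allele:
            raise ValidationError("empty allele designation")


@dataclass
class LocusObservation:
    locus: str
    peaks: list[Peak] = field(default_factory=list)

    def __post_init__(self):
        labels = [p.allele for p in self.peaks]
        if len(labels) != len(set(labels)):
            raise ValidationError(f"duplicate allele labels at {self.locus}")

    @property
    def alleles(self) -> list[str]:
        return [p.allele for p in self.peaks]

    def height(self, allele: str) -> float | None:
        for p in self.peaks:
            if p.allele == allele:
                return p.height
        return None

    def mean_size(self) -> float | None:
        sizes = [p.size for p in self.peaks if p.size is not None]
        return sum(sizes) / len(sizes) if sizes else None


@dataclass
class STRProfile:
    """A typed profile: evidence (with peak heights) or reference genotypes."""

    sample_id: str
    loci: dict[str, LocusObservation] = field(default_factory=dict)
    kind: str = "evidence"  # "evidence" | "reference"
    metadata: dict = field(default_factory=dict)

    def genotype(self, locus: str) -> tuple[str, str]:
        """Reference genotype at *locus*; a single listed allele is read as
        homozygous (standard forensic convention)."""
        obs = self.loci[locus]
        alleles = obs.alleles
        if not 1 <= len(alleles) <= 2:
            raise ValidationError(
                f"reference {self.sample_id} has {len(alleles)} alleles at {locus}"
            )
        if len(alleles) == 1:
            return (alleles[0], alleles[0])
        return tuple(sorted(alleles, key=_allele_sort_key))  # type: ignore[return-value]


def _allele_sort_key(a: str):
    try:
        return (0, float(a))
    except ValueError:
        return (1, a)


# ---------------------------------------------------------------------------
# frequency tables
# ---------------------------------------------------------------------------

@dataclass
class FrequencyTable:
    """Per-locus allele frequencies with a floor for unseen alleles.

    The floor defaults to 5/(2N) with N the survey size (the usual minimum
    allele frequency convention).
    """

    freqs: dict[str, dict[str, float]]
    floor: float = 5.0 / (2 * 500)

    def __post_init__(self):
        for locus, table in self.freqs.items():
            for a, f in table.items():
                if f < 0:
                    raise ValidationError(f"negative frequency {f} at {locus}:{a}")
            s = sum(table.values())
            if s > 1 + 1e-6:
                raise ValidationError(f"frequencies at {locus} sum to {s} > 1")

    def freq(self, locus: str, allele: str) -> float:
        """Floored population frequency of one allele."""
        table = self.freqs.get(locus)
        if table is None:
            raise ValidationError(f"locus {locus} not in frequency table")
        f = table.get(allele)
        if f is None:
            logger.warning("allele %s not in table for %s; floor %.4g used",
                           allele, locus, self.floor)
            return self.floor
        return max(f, self.floor)

    def residual(self, locus: str, alleles) -> float:
        """Frequency mass of the aggregate unobserved allele Q, relative to
        the explicit candidate set *alleles*."""
        return max(0.0, 1.0 - sum(self.freq(locus, a) for a in alleles))

    def alleles(self, locus: str) -> list[str]:
        return sorted(self.freqs[locus], key=_allele_sort_key)


def read_frequency_table(path, floor: float | None = None,
                         survey_size: int = 500) -> FrequencyTable:
    """Read a CSV with columns locus, allele, frequency."""
    df = pd.read_csv(path, dtype={"allele": str})
    for col in ("locus", "allele", "frequency"):
        if col not in df.columns:
            raise FormatError(f"frequency table missing column {col!r}")
    freqs: dict[str, dict[str, float]] = {}
    for row in df.itertuples(index=False):
        freqs.setdefault(row.locus, {})[str(row.allele)] = float(row.frequency)
    if floor is None:
        floor = 5.0 / (2 * survey_size)
    return FrequencyTable(freqs=freqs, floor=floor)


def write_frequency_table(table: FrequencyTable, path) -> None:
    rows = [
        {"locus": locus, "allele": a, "frequency": f}
        for locus, d in table.freqs.items()
        for a, f in d.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# kit size maps
# ---------------------------------------------------------------------------

@dataclass
class KitMap:
    """Maps allele designations to fragment sizes per locus.

    size(locus, allele) = offset + motif * repeats + fractional part, e.g.
    allele "9.3" with offset 60, motif 4 sits at 60 + 4*9 + 3 = 99 bp.
    """

    loci: dict[str, dict]  # locus -> {offset, motif, dye}

    def size(self, locus: str, allele: str) -> float:
        spec = self.loci.get(locus)
        if spec is None:
            raise ValidationError(f"locus {locus} not in kit map")
        m = re.fullmatch(r"(\d+)(?:\.(\d+))?", allele)
        if not m:
            raise ValidationError(f"allele {allele!r} is not a numeric designation")
        repeats = int(m.group(1))
        frac = int(m.group(2)) if m.group(2) else 0
        size = spec["offset"] + spec["motif"] * repeats + frac
        if size <= 0:
            raise ValidationError(f"non-positive size for {locus}:{allele}")
        return float(size)

    def mean_size(self, locus: str, typical_repeats: float = 12.0) -> float:
        """Nominal fragment size at a typical repeat count; used for the Q
        allele when a locus has no observed peak to average over."""
        spec = self.loci[locus]
        return float(spec["offset"] + spec["motif"] * typical_repeats)


def read_kit_map(path) -> KitMap:
    """Read a kit map from YAML (mapping) or CSV (locus,offset_bp,motif_bp,dye)."""
    path = str(path)
    if path.endswith((".yaml", ".yml")):
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        loci = {
            locus: {"offset": float(d["offset_bp"]), "motif": float(d["motif_bp"]),
                    "dye": d.get("dye", "")}
            for locus, d in raw.items()
        }
    else:
        df = pd.read_csv(path)
        for col in ("locus", "offset_bp", "motif_bp"):
            if col not in df.columns:
                raise FormatError(f"kit map missing column {col!r}")
        loci = {
            r.locus: {"offset": float(r.offset_bp), "motif": float(r.motif_bp),
                      "dye": getattr(r, "dye", "")}
            for r in df.itertuples(index=False)
        }
    return KitMap(loci=loci)


def write_kit_map(kit: KitMap, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {locus: {"offset_bp": d["offset"], "motif_bp": d["motif"],
                     "dye": d.get("dye", "")}
             for locus, d in kit.loci.items()}, fh)


# ---------------------------------------------------------------------------
# GeneMapper genotype tables
# ---------------------------------------------------------------------------

def read_genemapper(path, layout: str = "wide", kind: str = "evidence"
                    ) -> dict[str, STRProfile]:
    """Read a GeneMapper-style tab-delimited genotype table.

    ``layout="wide"`` expects columns Sample Name, Marker, Allele 1..n,
    Height 1..n, Size 1..n (one row per sample/locus). ``layout="long"``
    expects one row per allele with columns Sample Name, Marker, Allele,
    Height, Size. Returns one profile per sample id.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("Sample Name", "Marker"):
        if col not in df.columns:
            raise FormatError(f"GeneMapper table missing column {col!r}")
    profiles: dict[str, STRProfile] = {}
    if layout == "wide":
        allele_cols = sorted((c for c in df.columns if re.fullmatch(r"Allele \d+", c)),
                             key=lambda c: int(c.split()[1]))
        if not allele_cols:
            raise FormatError("GeneMapper table missing column 'Allele 1'")
        height_cols = [c.replace("Allele", "Height") for c in allele_cols]
        size_cols = [c.replace("Allele", "Size") for c in allele_cols]
        for i, row in enumerate(df.itertuples(index=False), start=2):
            rec = dict(zip(df.columns, row))
            sample, marker = rec["Sample Name"], rec["Marker"]
            peaks = []
            for ac, hc, sc in zip(allele_cols, height_cols, size_cols):
                a = rec.get(ac)
                if a is None or (isinstance(a, float) and math.isnan(a)) or str(a).strip() == "":
                    continue
                h = _parse_number(rec.get(hc), "height", i) if kind == "evidence" else None
                s = _parse_number(rec.get(sc), "size", i)
                peaks.append(Peak(allele=str(a).strip(), height=h, size=s))
            prof = profiles.setdefault(sample, STRProfile(sample_id=sample, kind=kind))
            prof.loci[marker] = LocusObservation(locus=marker, peaks=peaks)
    elif layout == "long":
        for i, row in enumerate(df.itertuples(index=False), start=2):
            rec = dict(zip(df.columns, row))
            sample, marker = rec["Sample Name"], rec["Marker"]
            prof = profiles.setdefault(sample, STRProfile(sample_id=sample, kind=kind))
            obs = prof.loci.setdefault(marker, LocusObservation(locus=marker))
            h = _parse_number(rec.get("Height"), "height", i) if kind == "evidence" else None
            s = _parse_number(rec.get("Size"), "size", i)
            obs.peaks.append(Peak(allele=str(rec["Allele"]).strip(), height=h, size=s))
    else:
        raise ValueError(f"unknown layout {layout!r}")
    if not profiles:
        logger.warning("GeneMapper file %s contained zero data rows", path)
    return profiles


def _parse_number(value, what: str, line: int) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    text = str(value).strip()
    if not text:
        return None
    try:
        return float(text)
    except ValueError:
        raise FormatError(f"line {line}: non-numeric {what} {value!r}") from None


def write_genemapper(profiles, path) -> None:
    """Write profiles as a wide-layout GeneMapper-style table."""
    if isinstance(profiles, STRProfile):
        profiles = [profiles]
    n = max((len(o.peaks) for p in profiles for o in p.loci.values()), default=1)
    cols = (["Sample Name", "Marker"]
            + [f"Allele {i+1}" for i in range(n)]
            + [f"Height {i+1}" for i in range(n)]
            + [f"Size {i+1}" for i in range(n)])
    rows = []
    for p in profiles:
        for marker, obs in p.loci.items():
            rec = {"Sample Name": p.sample_id, "Marker": marker}
            for i, peak in enumerate(obs.peaks):
                rec[f"Allele {i+1}"] = peak.allele
                if peak.height is not None:
                    rec[f"Height {i+1}"] = f"{peak.height:.1f}"
                if peak.size is not None:
                    rec[f"Size {i+1}"] = f"{peak.size:.2f}"
            rows.append(rec)
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def apply_analytical_threshold(profile: STRProfile, at: float = DEFAULT_AT
                               ) -> STRProfile:
    """Remove peaks below the analytical threshold (idempotent)."""
    if at <= 0:
        raise ValidationError(f"analytical threshold must be positive, got {at}")
    out = STRProfile(sample_id=profile.sample_id, kind=profile.kind,
                     metadata=dict(profile.metadata))
    for locus, obs in profile.loci.items():
        kept = [p for p in obs.peaks if p.height is None or p.height >= at]
        dropped = len(obs.peaks) - len(kept)
        if dropped:
            logger.info("AT=%g removed %d peak(s) at %s", at, dropped, locus)
        out.loci[locus] = LocusObservation(locus=locus, peaks=kept)
    return out


# ---------------------------------------------------------------------------
# canonical profile JSON
# ---------------------------------------------------------------------------

def profile_to_json(profile: STRProfile) -> dict:
    return {
        "sample_id": profile.sample_id,
        "kind": profile.kind,
        "loci": {
            locus: [[p.allele, p.height, p.size] for p in obs.peaks]
            for locus, obs in profile.loci.items()
        },
        "metadata": profile.metadata,
    }


def profile_from_json(data: dict) -> STRProfile:
    prof = STRProfile(sample_id=data["sample_id"], kind=data.get("kind", "evidence"),
                      metadata=data.get("metadata", {}))
    for locus, peaks in data["loci"].items():
        prof.loci[locus] = LocusObservation(
            locus=locus, peaks=[Peak(allele=a, height=h, size=s) for a, h, s in peaks])
    return prof


def write_profile_json(profile: STRProfile, path) -> None:
    with open(path, "w") as fh:
        json.dump(profile_to_json(profile), fh, indent=1)


def read_profile_json(path) -> STRProfile:
    with open(path) as fh:
        return profile_from_json(json.load(fh))
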