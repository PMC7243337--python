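"""Format adapters: BED, FASTA, JASPAR, TSV tables and the flat config file.

All tabular output is written with fixed float formatting so that repeated
runs of the same configuration produce byte-identical files.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import asdict

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .chec_sim import FragmentPopulation, LaneId

log = logging.getLogger("telochec")


def configure_logging(level: str = "INFO") -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.handlers[:] = [handler]
    log.setLevel(level.upper())


# -- BED --------------------------------------------------------------------


def write_features_bed(template, path) -> None:
    """Template features as BED6 (0-based half-open, kind in the name column)."""
    with open(path, "w") as fh:
        for f in sorted(template.features, key=lambda f: f.start):
            fh.write(
                f"{template.name}\t{f.start}\t{f.end}\t{f.kind}:{f.name}\t0\t+\n"
            )


def write_sites_bed(sites, path, score_of=None) -> None:
    """Consolidated sites as BED6; score column defaults to n_observations."""
    with open(path, "w") as fh:
        for s in sorted(sites, key=lambda s: s.mean_offset):
            start = int(round(s.mean_offset))
            score = int(score_of(s)) if score_of else s.n_observations
            fh.write(
                f"{s.template or 'site'}\t{start}\t{start + 1}\tsite_{s.label}\t{score}\t+\n"
            )


def write_calls_bed(sites, path, chrom: str = "seq", cap: float = 30.0) -> None:
    """PWM site calls as BED6 with score = -log10 p (capped)."""
    with open(path, "w") as fh:
        for s in sites:
            score = cap if s.p_value <= 0 else min(cap, -np.log10(s.p_value))
            name = s.matrix_id or "site"
            end = s.position + 1
            fh.write(f"{chrom}\t{s.position}\t{end}\t{name}\t{score:.2f}\t{s.strand}\n")


def read_bed(path) -> list[tuple[str, int, int, str, float, str]]:
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: malformed BED record")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as e:
                raise ValueError(f"{path}:{ln}: non-integer coordinates") from e
            name = parts[3] if len(parts) > 3 else "."
            score = float(parts[4]) if len(parts) > 4 else 0.0
            strand = parts[5] if len(parts) > 5 else "+"
            out.append((parts[0], start, end, name, score, strand))
    return out


# -- FASTA ------------------------------------------------------------------


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, path, "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


# -- lanes / tables ---------------------------------------------------------


def lanes_to_frame(populations) -> pd.DataFrame:
    rows = []
    for pop in populations:
        lengths, counts = np.unique(np.round(pop.fragments, 3), return_counts=True)
        for L, c in zip(lengths, counts):
            rows.append(
                {
                    "template": pop.lane.template,
                    "genotype": pop.lane.genotype,
                    "construct": pop.lane.construct,
                    "time_min": pop.lane.time,
                    "temperature": pop.lane.temperature,
                    "fragment_bp": L,
                    "count": int(c),
                    "n_molecules": pop.n_molecules,
                }
            )
    return pd.DataFrame(rows)


def write_lanes_tsv(populations, path) -> None:
    lanes_to_frame(populations).to_csv(path, sep="\t", index=False, float_format="%.3f")


def read_lanes_tsv(path) -> list[FragmentPopulation]:
    df = pd.read_csv(path, sep="\t")
    pops = []
    keys = ["template", "genotype", "construct", "time_min", "temperature"]
    for vals, grp in df.groupby(keys, sort=False):
        lane = LaneId(vals[0], vals[1], vals[2], float(vals[3]), vals[4])
        frags = np.repeat(grp["fragment_bp"].to_numpy(float), grp["count"].to_numpy(int))
        pops.append(FragmentPopulation(lane, frags, int(grp["n_molecules"].iloc[0])))
    return pops


def sites_to_frame(sites) -> pd.DataFrame:
    return pd.DataFrame([asdict(s) for s in sites])


def intervals_to_frame(intervals) -> pd.DataFrame:
    return pd.DataFrame([asdict(iv) for iv in intervals])


def bands_to_frame(lane_bands: dict) -> pd.DataFrame:
    rows = []
    for lane, bands in lane_bands.items():
        for b in bands:
            rows.append(
                {
                    "lane": str(lane),
                    "position": b.position,
                    "size_bp": b.size,
                    "percent_signal": b.percent_signal,
                    "prominence": b.prominence,
                }
            )
    return pd.DataFrame(rows)


def profile_to_tsv(profile, path) -> None:
    pd.DataFrame(
        {"position": profile.positions, "intensity": profile.intensity}
    ).to_csv(path, sep="\t", index=False, float_format="%.6f")


# -- flat config ------------------------------------------------------------

CONFIG_KEYS = {
    "templates": "comma-separated template names",
    "constructs": "comma-separated MN construct names",
    "genotype": "WT | sir | yku",
    "n_molecules": "molecules simulated per lane",
    "base_rate": "k, cuts per accessible bp per minute at 30 C",
    "seed": "master seed; every stage derives from it",
    "tolerance": "site clustering tolerance, bp",
    "min_prominence": "band-calling prominence, fraction of lane max",
    "h2a_cold_prominence": "prominence for H2A-MN 4C lanes",
    "classifier_threshold": "nucleosome spacing threshold, bp",
    "ladder_noise": "ladder position noise SD, profile units",
    "outdir": "output directory",
}


def read_config(path) -> dict:
    """Flat ``key = value`` config; lists are comma-separated."""
    out: dict = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{ln}: expected 'key = value'")
            key, _, raw = line.partition("=")
            key, raw = key.strip(), raw.strip()
            if key not in CONFIG_KEYS:
                raise ValueError(f"{path}:{ln}: unknown key {key!r}")
            if "," in raw:
                out[key] = tuple(v.strip() for v in raw.split(",") if v.strip())
            else:
                out[key] = _coerce(raw)
    return out


def write_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        for key, value in cfg.items():
            if isinstance(value, (tuple, list)):
                value = ",".join(map(str, value))
            fh.write(f"{key} = {value}\n")


def _coerce(raw: str):
    for typ in (int, float):
        try:
            return typ(raw)
        except ValueError:
            pass
    return raw
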