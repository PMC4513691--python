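"""UCSC Assembly/Track Hub construction and validation.

A Track Hub is a directory tree (hub.txt, genomes.txt,
<genome>/trackDb.txt plus data files) that the UCSC genome browser loads
from a web-accessible location. An Assembly Hub additionally carries the
genome sequence itself, so custom organisms can be displayed.

Outputs are deterministic byte-for-byte for a given config: fixed key
order, no timestamps. Binary encoders (2bit, bigWig, bigBed) are
external; when the genome cannot be 2bit-encoded the FASTA is shipped and
the manifest notes the pending conversion.
"""

from __future__ import annotations

import shutil
from dataclasses import dataclass, field
from pathlib import Path

from pyfaidx import Fasta

__all__ = ["TrackSpec", "HubConfig", "build_track_hub", "build_assembly_hub", "validate_hub"]

VISIBILITIES = ("hide", "dense", "squish", "pack", "full")
TRACK_TYPES = ("bigWig", "bam", "bedGraph")  # plus "bigBed N"


def _is_valid_type(t: str) -> bool:
    if t in TRACK_TYPES:
        return True
    parts = t.split()
    return parts[0] == "bigBed" and (len(parts) == 1 or parts[1].isdigit())


@dataclass(frozen=True)
class TrackSpec:
    track_id: str
    file_path: str
    type: str = "bigWig"
    short_label: str = ""
    long_label: str = ""
    color: str = "0,0,0"
    visibility: str = "pack"

    def __post_init__(self) -> None:
        if not self.track_id or any(c.isspace() for c in self.track_id):
            raise ValueError(f"track_id must be a whitespace-free token, got {self.track_id!r}")
        if not _is_valid_type(self.type):
            raise ValueError(f"unsupported track type {self.type!r}")
        if self.visibility not in VISIBILITIES:
            raise ValueError(f"visibility must be one of {VISIBILITIES}")


@dataclass
class HubConfig:
    hub_id: str
    genome_id: str
    short_label: str = ""
    long_label: str = ""
    email: str = "nobody@example.org"
    base_url: str = ""
    genome_fasta: str | None = None
    default_pos: str | None = None
    organism: str = "unknown"
    scientific_name: str = "unknown"
    description: str = ""
    tracks: list = field(default_factory=list)

    def __post_init__(self) -> None:
        for tok, label in ((self.hub_id, "hub_id"), (self.genome_id, "genome_id")):
            if not tok or any(c.isspace() for c in tok):
                raise ValueError(f"{label} must be a whitespace-free token, got {tok!r}")
        if not self.base_url:
            raise ValueError("base_url must be non-empty")
        ids = [t.track_id for t in self.tracks]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate track_id in {ids}")


def _write_text(path: Path, text: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(text, newline="\n")


def _hub_txt(config: HubConfig) -> str:
    return (
        f"hub {config.hub_id}\n"
        f"shortLabel {config.short_label or config.hub_id}\n"
        f"longLabel {config.long_label or config.short_label or config.hub_id}\n"
        "genomesFile genomes.txt\n"
        f"email {config.email}\n"
    )


def _trackdb_txt(config: HubConfig) -> str:
    stanzas = []
    base = config.base_url.rstrip("/")
    for t in config.tracks:
        fname = Path(t.file_path).name
        stanzas.append(
            f"track {t.track_id}\n"
            f"bigDataUrl {base}/{config.genome_id}/{fname}\n"
            f"shortLabel {t.short_label or t.track_id}\n"
            f"longLabel {t.long_label or t.short_label or t.track_id}\n"
            f"type {t.type}\n"
            f"color {t.color}\n"
            f"visibility {t.visibility}\n"
        )
    return "\n".join(stanzas)


def _copy_tracks(config: HubConfig, genome_dir: Path, manifest: list) -> None:
    for t in config.tracks:
        src = Path(t.file_path)
        if not src.exists():
            raise FileNotFoundError(f"track file missing: {t.file_path}")
        dst = genome_dir / src.name
        shutil.copyfile(src, dst)
        manifest.append(str(dst))


def build_track_hub(config: HubConfig, out_dir) -> list:
    """Write a complete Track Hub under ``out_dir``; returns paths written."""
    out = Path(out_dir)
    genome_dir = out / config.genome_id
    genome_dir.mkdir(parents=True, exist_ok=True)
    manifest: list = []

    _copy_tracks(config, genome_dir, manifest)

    _write_text(out / "hub.txt", _hub_txt(config))
    manifest.append(str(out / "hub.txt"))
    _write_text(
        out / "genomes.txt",
        f"genome {config.genome_id}\ntrackDb {config.genome_id}/trackDb.txt\n",
    )
    manifest.append(str(out / "genomes.txt"))
    _write_text(genome_dir / "trackDb.txt", _trackdb_txt(config))
    manifest.append(str(genome_dir / "trackDb.txt"))
    return manifest


def _default_pos(fasta: Fasta) -> str:
    name = list(fasta.keys())[0]
    return f"{name}:1-{min(len(fasta[name]), 1000)}"


def build_assembly_hub(config: HubConfig, out_dir) -> list:
    """Write an Assembly Hub: a Track Hub plus the genome sequence.

    genomes.txt gains twoBitPath, organism, defaultPos, scientificName and
    description; no 2bit encoder is bundled, so the FASTA itself is shipped
    and a manifest note records the pending conversion.
    """
    if not config.genome_fasta:
        raise ValueError("assembly hubs require genome_fasta")
    fasta_src = Path(config.genome_fasta)
    fa = Fasta(str(fasta_src))

    out = Path(out_dir)
    genome_dir = out / config.genome_id
    genome_dir.mkdir(parents=True, exist_ok=True)
    manifest: list = []

    _copy_tracks(config, genome_dir, manifest)

    genome_file = f"{config.genome_id}.fa"
    shutil.copyfile(fasta_src, genome_dir / genome_file)
    manifest.append(str(genome_dir / genome_file))
    manifest.append(f"NOTE: {genome_file} awaits 2bit encoding (no encoder available)")

    default_pos = config.default_pos or _default_pos(fa)
    _write_text(out / "hub.txt", _hub_txt(config))
    manifest.append(str(out / "hub.txt"))
    _write_text(
        out / "genomes.txt",
        f"genome {config.genome_id}\n"
        f"trackDb {config.genome_id}/trackDb.txt\n"
        f"twoBitPath {config.genome_id}/{genome_file}\n"
        f"organism {config.organism}\n"
        f"defaultPos {default_pos}\n"
        f"scientificName {config.scientific_name}\n"
        f"description {config.description or config.long_label or config.hub_id}\n"
        f"groups {config.genome_id}/groups.txt\n",
    )
    manifest.append(str(out / "genomes.txt"))
    _write_text(
        genome_dir / "groups.txt",
        "name default\nlabel Default\npriority 1\ndefaultIsClosed 0\n",
    )
    manifest.append(str(genome_dir / "groups.txt"))
    _write_text(genome_dir / "trackDb.txt", _trackdb_txt(config))
    manifest.append(str(genome_dir / "trackDb.txt"))
    return manifest


_HUB_REQUIRED = ("hub", "shortLabel", "longLabel", "genomesFile", "email")
_GENOMES_REQUIRED = ("genome", "trackDb")
_TRACK_REQUIRED = ("track", "bigDataUrl", "shortLabel", "longLabel", "type", "visibility")


def _parse_stanzas(text: str) -> list:
    """Blank-line-separated stanzas of 'key value' lines -> list of dicts."""
    stanzas = []
    for block in text.split("\n\n"):
        lines = [l for l in block.splitlines() if l.strip()]
        if not lines:
            continue
        stanza = {}
        for line in lines:
            key, _, value = line.partition(" ")
            stanza[key] = value
        stanzas.append(stanza)
    return stanzas


def validate_hub(hub_dir) -> list:
    """Grammar-check a hub directory; returns a list of violation strings.

    Checks: required keys per file, referenced-file existence, track_id
    uniqueness. An empty list means the hub is valid.
    """
    hub_dir = Path(hub_dir)
    violations: list = []
    hub_txt = hub_dir / "hub.txt"
    if not hub_txt.exists():
        return [f"missing file: {hub_txt}"]
    hub_stanzas = _parse_stanzas(hub_txt.read_text())
    hub = hub_stanzas[0] if hub_stanzas else {}
    for key in _HUB_REQUIRED:
        if key not in hub:
            violations.append(f"hub.txt: missing required key '{key}'")
    genomes_rel = hub.get("genomesFile")
    if not genomes_rel:
        return violations
    genomes_txt = hub_dir / genomes_rel
    if not genomes_txt.exists():
        violations.append(f"hub.txt: genomesFile '{genomes_rel}' does not exist")
        return violations
    for stanza in _parse_stanzas(genomes_txt.read_text()):
        for key in _GENOMES_REQUIRED:
            if key not in stanza:
                violations.append(f"genomes.txt: missing required key '{key}'")
        for key in ("trackDb", "twoBitPath", "groups"):
            if key in stanza and not (hub_dir / stanza[key]).exists():
                violations.append(f"genomes.txt: {key} '{stanza[key]}' does not exist")
        trackdb_rel = stanza.get("trackDb")
        if not trackdb_rel or not (hub_dir / trackdb_rel).exists():
            continue
        genome_dir = (hub_dir / trackdb_rel).parent
        seen_ids = set()
        for ts in _parse_stanzas((hub_dir / trackdb_rel).read_text()):
            tid = ts.get("track", "<unnamed>")
            if tid in seen_ids:
                violations.append(f"trackDb.txt: duplicate track id '{tid}'")
            seen_ids.add(tid)
            for key in _TRACK_REQUIRED:
                if key not in ts:
                    violations.append(f"trackDb.txt: track '{tid}' missing key '{key}'")
            url = ts.get("bigDataUrl")
            if url and not (genome_dir / Path(url).name).exists():
                violations.append(
                    f"trackDb.txt: track '{tid}' bigDataUrl file '{Path(url).name}' "
                    "not present in hub"
                )
    return violations
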