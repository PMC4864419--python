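"""Explicit retrieval of deposited structures and shift tables.

Fetching is never implicit: analyses accept local paths, and this module
is only used when the caller asks for an accession by name.  Downloads
require network access; offline use relies on previously cached files.
"""

from __future__ import annotations

import urllib.request
from pathlib import Path
from typing import Optional

__all__ = ["accession_url", "cached_path", "fetch"]

#: deposited accessions of the PT duplex study
PDB_ACCESSIONS = {"5J3G": "PT-free", "5J3I": "[Sp,Sp]-PT", "5J3F": "[Rp,Rp]-PT"}
BMRB_ACCESSIONS = {"30053": "PT-free", "30054": "[Sp,Sp]-PT", "30052": "[Rp,Rp]-PT"}

DEFAULT_CACHE = Path.home() / ".cache" / "ptdna"


def accession_url(accession: str) -> str:
    acc = accession.upper()
    if acc in PDB_ACCESSIONS or (len(acc) == 4 and acc[0].isdigit()):
        return f"https://files.rcsb.org/download/{acc}.pdb"
    num = accession.lstrip("bmrBMR")
    if num.isdigit():
        return (
            "https://bmrb.io/ftp/pub/bmrb/entry_directories/"
            f"bmr{num}/bmr{num}_3.str"
        )
    raise ValueError(f"unrecognized accession {accession!r}")


def _filename(accession: str) -> str:
    acc = accession.upper()
    return f"{acc}.pdb" if len(acc) == 4 else f"bmr{accession.lstrip('bmrBMR')}_3.str"


def cached_path(accession: str, cache_dir: Optional[Path] = None) -> Optional[Path]:
    """Local copy of an accession if one exists (cache dir, then cwd)."""
    name = _filename(accession)
    for d in (Path(cache_dir) if cache_dir else DEFAULT_CACHE, Path.cwd()):
        p = d / name
        if p.exists():
            return p
    return None


def fetch(accession: str, cache_dir: Optional[Path] = None, timeout: float = 30.0) -> Path:
    """Return a local path for *accession*, downloading it if necessary.

    Raises ``RuntimeError`` with a clear message when the deposition is
    unavailable (e.g. no network); nothing in the package fetches
    implicitly.
    """
    hit = cached_path(accession, cache_dir)
    if hit is not None:
        return hit
    url = accession_url(accession)
    dest_dir = Path(cache_dir) if cache_dir else DEFAULT_CACHE
    dest_dir.mkdir(parents=True, exist_ok=True)
    dest = dest_dir / _filename(accession)
    try:
        with urllib.request.urlopen(url, timeout=timeout) as resp:
            dest.write_bytes(resp.read())
    except Exception as exc:
        raise RuntimeError(
            f"deposition {accession} unavailable: could not download {url} "
            f"({exc}); place the file at {dest} to work offline"
        ) from exc
    return dest
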