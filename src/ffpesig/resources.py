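"""Packaged gene lists.

Two plain-text resources ship with the package:

* ``ras_signature_18.txt`` — the 18-gene RAS/MEK/ERK pathway-activation
  panel whose per-sample mean is the composite signature score.  The token
  ``SLCO4A`` is kept exactly as printed in the published panel; it most
  likely denotes the HGNC symbol *SLCO4A1*.
* ``housekeeping_11.txt`` — the 11-gene reference (housekeeping) panel used
  for count normalization of NanoString-style data.
"""

from __future__ import annotations

from importlib import resources


def _read_gene_list(name: str) -> list[str]:
    text = resources.files("ffpesig.data").joinpath(name).read_text(encoding="utf-8")
    return [line.strip() for line in text.splitlines() if line.strip()]


def signature_genes() -> list[str]:
    """The 18-gene pathway-activation signature, in panel order."""
    return _read_gene_list("ras_signature_18.txt")


def housekeeping_genes() -> list[str]:
    """The 11-gene housekeeping (reference) panel."""
    return _read_gene_list("housekeeping_11.txt")
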