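"""Low-level sequence operations shared across the package.

Array probes interrogate bisulfite-treated DNA, so they live in a reduced
three-letter alphabet after processing; the helpers here implement the
reverse-complement and C->T conversion rules used everywhere else.
"""

from __future__ import annotations

# Degenerate codes R (A/G) and Y (C/T) occur in type II probe sequences at
# internal CpG positions; the complement table must carry them through.
_COMPLEMENT = str.maketrans("ACGTRYNacgtryn", "TGCAYRNtgcayrn")

PROBE_ALPHABET = frozenset("ACGTRY")
QUERY_ALPHABET = frozenset("AGT")


class SequenceError(ValueError):
    """A sequence violates the alphabet contract of an operation."""


def revcomp(seq: str) -> str:
    """Reverse complement over the probe alphabet (A/C/G/T/R/Y/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def bisulfite_convert(seq: str) -> str:
    """In-silico bisulfite conversion: every cytosine becomes thymine.

    Case is preserved; no other base is touched.
    """
    return seq.replace("C", "T").replace("c", "t")


def ct_collapse(base: str) -> str:
    """Collapse a single base into bisulfite-converted space.

    C and Y (C/T) both read as T after conversion; everything else is
    unchanged.  Used when comparing unconverted probe bases against the
    unconverted reference: two bases that agree after collapsing cannot be
    distinguished in a bisulfite experiment.
    """
    return "T" if base in ("C", "c", "Y", "y") else base.upper()
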