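"""Exception types.

``PedigreeError`` marks structural defects of the pedigree graph
(unresolved parents, cycles, duplicate identifiers); plain ``ValueError``
is used for invalid argument values.
"""


class PedigreeError(ValueError):
    """The pedigree violates a structural invariant."""
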