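"""Error types raised by dbcvkit.

All inherit from :class:`DbcvError` (itself a ``ValueError``) so callers can
catch the whole family with one clause; evaluation harnesses typically turn
these into not-applicable records rather than aborting a sweep.
"""


class DbcvError(ValueError):
    """Base class for all dbcvkit contract and validity errors."""


class DegenerateClusterError(DbcvError):
    """A cluster has fewer than two members, so its core distance is undefined."""


class InsufficientClustersError(DbcvError):
    """Fewer than two clusters remain after noise removal; DBCV is undefined."""


class UndefinedValidityError(DbcvError):
    """Both sparseness and separation vanish (all points of two clusters coincide)."""


class UndefinedTrendError(DbcvError):
    """A trend quantity cannot be computed (too few numeric entries, or a zero ARI change)."""
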