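"""Optional numba acceleration.

Numerical kernels that are quadratic in pedigree size (Meuwissen-Luo
inbreeding) are written as plain functions and jitted when numba is
importable; otherwise the pure-Python version runs, which is adequate for
small pedigrees.
"""

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(fn):
            return fn

        return wrap
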