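"""Independent brute-force re-derivation of the classification rules.

Written directly from the rule definitions as flat boolean expressions
over plain integers and strings — deliberately sharing no code with the
package — so that grid tests can compare the engine against a second,
independent route.
"""

PRIORITY = (
    "A-AMR", "CA-AMR", "A-TCMR", "CA-TCMR", "C-AMR-INACTIVE",
    "BC", "IFTA", "C4D-NO-REJECTION", "NO-REJECTION",
)

REJECTION = {"A-AMR", "CA-AMR", "EQUIVOCAL-AMR", "A-TCMR", "CA-TCMR"}


def oracle_applicable(t, i, v, g, ptc, c4d, abo, dsa,
                      t_ifta=0, i_ifta=0, cg=0, ci=0, ct=0):
    """Applicable category set; abo in {'compatible','incompatible'},
    dsa in {'+','-','unknown'}."""
    out = set()

    # --- acute TCMR grade / borderline / chronic-active TCMR
    if v == 3:
        grade = "III"
    elif v == 2:
        grade = "IIB"
    elif v == 1:
        grade = "IIA"
    elif i >= 2 and t == 3:
        grade = "IB"
    elif i >= 2 and t == 2:
        grade = "IA"
    else:
        grade = None
    ca_tcmr = i_ifta >= 2 and (t >= 2 or (t_ifta >= 2 and ct >= 2))
    borderline = (
        v == 0 and grade is None
        and ((t >= 1 and i <= 1) or (i >= 2 and t == 1))
    )
    if grade is not None:
        out.add("A-TCMR")
    if ca_tcmr:
        out.add("CA-TCMR")
    if borderline:
        out.add("BC")

    # --- AMR
    full_tcmr = grade is not None or ca_tcmr
    mvi = g + ptc
    c4d_ev = c4d >= 2 and abo == "compatible"
    strong = c4d_ev and mvi >= 2
    if g >= 1:
        c1 = True
    elif ptc >= 1:
        c1 = True
        if full_tcmr and not strong:
            c1 = False
        if abo == "incompatible" and dsa != "+":
            c1 = False
    else:
        c1 = False
    c2 = c4d_ev or mvi >= 2
    if c1 and c2:
        if cg >= 1:
            out.add("CA-AMR")
        elif dsa == "unknown" and not c4d_ev:
            out.add("EQUIVOCAL-AMR")
        else:
            out.add("A-AMR")

    # --- IFTA
    if max(ci, ct) >= 1:
        out.add("IFTA")

    # --- C4d without rejection
    if (c4d >= 2 and abo == "compatible"
            and not (out & REJECTION) and "IFTA" not in out):
        out.add("C4D-NO-REJECTION")

    return out


def oracle_primary(applicable):
    """Minimum-index category in the priority order; equivocal shares the
    A-AMR slot."""
    if not applicable:
        return "NO-REJECTION"
    rank = {c: k for k, c in enumerate(PRIORITY)}
    rank["EQUIVOCAL-AMR"] = rank["A-AMR"]
    return min(applicable, key=lambda c: rank[c])
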