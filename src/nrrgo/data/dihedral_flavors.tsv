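# Sequence-dependent pseudo-torsion cosine series, keyed by the class of the
# central residue pair (j,k) of dihedral i-j-k-l.  Classes: G = glycine,
# P = proline, X = all other residues.
# V(phi) = sum_n A_n * (1 + cos(n*phi - delta_n)), n = 1..4, A in kcal/mol,
# delta in degrees.
# SYNTHETIC RECONSTRUCTION: the knowledge-based, native-structure-independent
# torsion statistics behind sequence-flavored Go models are not tabulated in
# any packaged resource available here; these class-level coefficients are a
# reconstruction with the qualitative features of backbone torsion statistics
# (stiff generic backbone, floppy glycine, restricted proline).  The absolute
# scale is subsumed by the global thermal calibration of the model.
# A "uniform" row is provided as a sequence-independent fallback.
class	A1	delta1	A2	delta2	A3	delta3	A4	delta4
XX	0.30	120.0	0.18	180.0	0.12	0.0	0.06	0.0
XG	0.12	120.0	0.08	180.0	0.05	0.0	0.03	0.0
GX	0.12	120.0	0.08	180.0	0.05	0.0	0.03	0.0
GG	0.06	120.0	0.04	180.0	0.03	0.0	0.02	0.0
XP	0.45	100.0	0.30	180.0	0.15	0.0	0.08	0.0
PX	0.45	100.0	0.30	180.0	0.15	0.0	0.08	0.0
GP	0.30	100.0	0.20	180.0	0.10	0.0	0.05	0.0
PG	0.30	100.0	0.20	180.0	0.10	0.0	0.05	0.0
PP	0.55	100.0	0.35	180.0	0.18	0.0	0.09	0.0
uniform	0.20	120.0	0.10	180.0	0.06	0.0	0.03	0.0
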