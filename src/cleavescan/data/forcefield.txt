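# cleavescan bundled united-atom parameter set
#
# A small self-consistent table covering peptide backbones and generic
# side-chain beads (apolar hydrogens are folded into CH1/CH2/CH3 beads;
# only the amide hydrogen is explicit).  Units: C12 kJ mol^-1 nm^12,
# C6 kJ mol^-1 nm^6, charges e, bond k kJ mol^-1 nm^-2 with E=k(b-b0)^2,
# b0 nm, angle k kJ mol^-1 rad^-2 with E=k(t-t0)^2, t0 deg, torsion
# E=k(1+cos(m*phi-phase)), phase deg.
#
# [LJ] lines: TYPE C12 C6 (self pair; cross pairs combine geometrically)
#             or TYPE1 TYPE2 C12 C6 (explicit override).
# [BONDS]: TYPE1 TYPE2 k b0.  [ANGLES]: TYPE1 TYPE2 TYPE3 k theta0
# (end types order-insensitive).  [TORSIONS]: keyed by the two central
# atom types: TYPE1 TYPE2 k m phase.

[LJ]
O    7.4149e-07  2.2619e-03
N    2.3195e-06  2.4364e-03
C    4.9373e-06  2.3406e-03
CH1  9.7022e-05  6.0684e-03
CH2  3.3966e-05  7.4684e-03
CH3  2.6646e-05  9.6138e-03
H    0.0         0.0
# purely repulsive probe bead (steric obstructions in synthetic receptors)
CR   1.0e-05     0.0

[CHARGES]
N    -0.31
H     0.31
C     0.45
O    -0.45
CH1   0.00
CH2   0.00
CH3   0.00
CR    0.00

[BONDS]
C   N    1.0e5  0.133
C   O    1.0e5  0.123
CH1 N    1.0e5  0.147
CH2 N    1.0e5  0.147
C   CH1  1.0e5  0.153
C   CH2  1.0e5  0.153
CH1 CH3  1.0e5  0.153
CH1 CH2  1.0e5  0.153
C   CH3  1.0e5  0.152
CH3 N    1.0e5  0.147
H   N    4.0e5  0.100

[ANGLES]
N   CH1 C    250  111.0
N   CH2 C    250  112.5
CH1 C   N    250  116.0
CH2 C   N    250  116.0
CH3 C   N    250  115.0
C   N   CH1  250  122.0
C   N   CH2  250  122.0
C   N   CH3  250  122.0
CH1 C   O    250  121.0
CH2 C   O    250  121.0
CH3 C   O    250  121.0
O   C   N    250  123.0
C   N   H    250  119.0
CH1 N   H    250  118.0
CH2 N   H    250  118.0
CH3 N   H    250  118.0
N   CH1 CH3  250  110.5
N   CH1 CH2  250  110.5
C   CH1 CH3  250  110.5
C   CH1 CH2  250  110.5

[TORSIONS]
CH1 N    1.0   3  0
CH2 N    1.0   3  0
C   CH1  1.0   3  0
C   CH2  1.0   3  0
C   N    33.5  2  180
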