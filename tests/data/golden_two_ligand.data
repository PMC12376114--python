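LAMMPS data file. ligandshell monolayer snapshot
#meta {"shell_count": 1, "lattice_constant": 4.08, "trim": 2, "ligands": [["PEG", 0], ["DDT", 6]], "provenance": {"fixture": "golden"}}
# types: 1=Au 2=S 3=CH2 4=CH3 5=O_ether

32 atoms
17 bonds

5 atom types
1 bond types

-33.0 33.0 xlo xhi
-33.0 33.0 ylo yhi
-33.0 33.0 zlo zhi

Masses

1 196.96657
2 32.06000
3 14.02700
4 15.03500
5 15.99900

Atoms # full

1 0 1 0.000000 -2.454124 0.000000 -1.516732
2 0 1 0.000000 -2.454124 0.000000 1.516732
3 0 1 0.000000 -1.516732 -2.454124 0.000000
4 0 1 0.000000 -1.516732 2.454124 0.000000
5 0 1 0.000000 0.000000 -1.516732 -2.454124
6 0 1 0.000000 0.000000 -1.516732 2.454124
7 0 1 0.000000 0.000000 1.516732 -2.454124
8 0 1 0.000000 0.000000 1.516732 2.454124
9 0 1 0.000000 1.516732 -2.454124 0.000000
10 0 1 0.000000 1.516732 2.454124 0.000000
11 0 1 0.000000 2.454124 0.000000 -1.516732
12 0 1 0.000000 2.454124 0.000000 1.516732
13 0 1 0.000000 0.000000 0.000000 0.000000
14 1 2 0.000000 -4.708349 0.000000 -2.909919
15 1 3 0.000000 -5.487075 0.000000 -4.543836
16 1 3 0.250000 -7.012803 0.000000 -4.515006
17 1 5 -0.500000 -7.564471 0.000000 -5.812605
18 1 3 0.250000 -8.973252 0.000000 -5.753990
19 1 4 0.000000 -9.570305 0.000000 -7.158342
20 2 2 0.000000 0.000000 2.909919 -4.708349
21 2 3 0.000000 0.000000 2.875724 -6.518025
22 2 3 0.000000 0.000000 4.253269 -7.174565
23 2 3 0.000000 0.000000 4.197816 -8.699557
24 2 3 0.000000 0.000000 5.586610 -9.331956
25 2 3 0.000000 0.000000 5.531157 -10.856948
26 2 3 0.000000 0.000000 6.919951 -11.489346
27 2 3 0.000000 0.000000 6.864497 -13.014338
28 2 3 0.000000 0.000000 8.253291 -13.646737
29 2 3 0.000000 0.000000 8.197838 -15.171729
30 2 3 0.000000 0.000000 9.586632 -15.804127
31 2 3 0.000000 0.000000 9.531179 -17.329119
32 2 4 0.000000 0.000000 10.919973 -17.961518

Bonds

1 1 14 15
2 1 15 16
3 1 16 17
4 1 17 18
5 1 18 19
6 1 20 21
7 1 21 22
8 1 22 23
9 1 23 24
10 1 24 25
11 1 25 26
12 1 26 27
13 1 27 28
14 1 28 29
15 1 29 30
16 1 30 31
17 1 31 32
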