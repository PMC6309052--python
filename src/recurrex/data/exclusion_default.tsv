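# function-word CUIs removed when re-deriving the positive set
C3999001	The
C3999002	Then
C3999003	To
C3999004	After
C3999005	With
C3999006	Her
C3999007	She
C3999008	Was
C3999009	Who
C3999010	Now
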