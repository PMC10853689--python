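package_id,option_a,option_b,option_c
1,INTA Matagalpa,INTA Ferroso,INTA Chinandega
2,INTA Centro Sur,INTA Sur,INTA Ferroso Sequía
3,INTA Fuerte Sequía,INTA Sequía,INTA Negro
4,INTA Rojo,INTA Chinandega,INTA Centro Sur
5,INTA Sequía,INTA Ferroso Sequía,INTA Rojo
6,INTA Ferroso,INTA Matagalpa,INTA Sur
7,INTA Negro,INTA Centro Sur,INTA Fuerte Sequía
8,INTA Fuerte Sequía,INTA Rojo,INTA Ferroso
9,INTA Chinandega,INTA Negro,INTA Matagalpa
10,INTA Ferroso Sequía,INTA Chinandega,INTA Sequía
11,INTA Sur,INTA Fuerte Sequía,INTA Ferroso Sequía
12,INTA Matagalpa,INTA Centro Sur,INTA Sequía
13,INTA Ferroso,INTA Sur,INTA Negro
14,INTA Rojo,INTA Fuerte Sequía,INTA Matagalpa
15,INTA Centro Sur,INTA Sequía,INTA Ferroso
16,INTA Sur,INTA Negro,INTA Chinandega
17,INTA Ferroso Sequía,INTA Ferroso,INTA Fuerte Sequía
18,INTA Rojo,INTA Matagalpa,INTA Centro Sur
19,INTA Sequía,INTA Rojo,INTA Sur
20,INTA Chinandega,INTA Ferroso Sequía,INTA Negro
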