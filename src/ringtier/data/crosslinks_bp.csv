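Protein1,Residue1,Protein2,Residue2,Annotation
EcDnaB,373,EcDnaB,175,ALAKELNVPVVALSQLNR(4)-ANKDEGPK(3)
EcDnaB,167,EcDnaB,175,VFKIAESR(3)-ANKDEGPK(3)
EcDnaB,217,EcDnaB,283,KTAGLQPSDLIIVAAR(1)-VDQTKIR(5)
EcDnaB,307,EcDnaB,283,ISGTMGILLEKR(11)-VDQTKIR(5)
EcDnaB,373,EcDnaB,167,ALAKELNVPVVALSQLNR(4)-VFKIAESR(3)
EcDnaB,373,EcDnaB,2,ALAKELNVPVVALSQLNR(4)-AGNKPFNK(1) residue 2 unmodelled
EcDnaB,180,EcDnaB,167,ANKDEGPKNIADVLDATVAR(8)-VFKIAESR(3)
EcDnaB,180,EcDnaB,373,ANKDEGPKNIADVLDATVAR(8)-ALAKELNVPVVALSQLNR(4)
lambdaP,177,EcDnaB,395,KAADELVHMTAR(1)-ADKRPVNSDLR(3)
lambdaP,200,EcDnaB,283,GEAIPEPVKQLPVMGGR(9)-VDQTKIR(5)
lambdaP,200,EcDnaB,217,INRGEAIPEPVKQLPVMGGR(12)-KTAGLQPSDLIIVAAR(1)
EcDnaB,175,lambdaP,229,ANKDEGPK(3)-FGLKGASV(4)
EcDnaB,2,lambdaP,229,AGNKPFNK(1)-FGLKGASV(4) residue 2 unmodelled
EcDnaB,167,lambdaP,229,VFKIAESR(3)-FGLKGASV(4)
EcDnaB,373,lambdaP,200,ALAKELNVPVVALSQLNR(4)-GEAIPEPVKQLPVMGGR(9)
EcDnaB,373,lambdaP,229,ALAKELNVPVVALSQLNR(4)-FGLKGASV(4)
lambdaP,218,lambdaP,225,AQALAKIAEIK(6)-AKFGLK(2)
lambdaP,229,lambdaP,223,FGLKGASV(4)-IAEIKAK(5)
lambdaP,200,lambdaP,177,GEAIPEPVKQLPVMGGR(9)-KAADELVHMTAR(1)
lambdaP,30,lambdaP,2,IANNMPEQYDEKPQVQQVAQIINGVFSQLLATFPASLANR(12)-MKNIAAQMVNFDR(2) residues 2/30 unmodelled
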