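>toy1 synthetic toy reference proteome sequence
RYTKLVSMEECQHDETRKGLIFDFFTPQQWTFKQLYMMMFRWRKDKDNGLCLNQSMNTDE
STTRFIHPHCPLCHADCAIGTHGKGRDCTFLSDNDIGCVIRKTSEQQWSCDTNCELVYWI
HIVEYRYTVALWTCCTSEFFASFHQKGSALHMMVGILKCEMVSIVVFPIFTWWSMWECMD
RRRHIES
>toy2 synthetic toy reference proteome sequence
RFEEWSHAYTPAHWQDYKPFFEGNNFRTPTWSKMILGAKIYNCLAYHIQVYAGEELHGVT
PATTVQSMPFDEMPCCNANYARDATLWWWGHIWGECIVVTRFNGNKFETDFKHDMKQSTV
YMESCCEADHSRDNKRGGKETTAPAWAAWGLTTVEADYFLCGII
>toy3 synthetic toy reference proteome sequence
EIHMKTPLPEDEIGFYNKTMKTPGSMPDCDQWFDCPTGPHGRIGTIIKVMSKARTNHKTA
YHQTCENWFMLPWNCFPHSAIGQLMWNFGMLTFMHGEEDDTHWYMDEQCFRHWGFLMFHV
CLKPNHAQCIRQKKCINRTAKLYDTHMGICKPYYWHDSLVLYNHVEFTLIGGISVACHCT
CYLCLEGLAMCQGIKADA
>toy4 synthetic toy reference proteome sequence
IYTCGPMTTRNNAAGPAWDGWMFDVQPSHNAEVYHDMLSTFTCIKPKQVIAATFNKRSKE
FCMTILCASPCGGDHISCHITFLELAINFWAQRDEGLTVLIPTCKIWCWPDVLEMVSHPE
NNEC
>toy5 synthetic toy reference proteome sequence
PTTHVACSTVRACPEKYGTSCDTLFSECYELFLLLMFGYKGYWEYRFVPMGCYCYECEGN
PIYEKFIDKRVGTYYKCHMAGIGESQKIPSHRETCFCREATKEGVLSSHLLLKANRETSQ
SFCAVDEKLDIVHPEVWSFAQTFPSVNWRTNNHLISQPHTMAWKHG
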